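"""Synthetic bisulfite-sequencing data with plant-methylome structure.

Generates everything the analysis consumes, at desk scale: a random genome
with a TE-dense pericentromeric compartment, TE/PCG annotations with family
labels, a latent per-site methylation probability ("true methylome") with
compartment- and context-specific means, observed call tables via Poisson
coverage and binomial read sampling with a bisulfite non-conversion error,
and an F2 mapping population for segregation and bulked-segregant analysis.

Mutant methylomes follow one of two models:

* ``uniform_proportional`` — every site's true probability is scaled by a
  per-context factor. The defaults f_CG = 0.76, f_CHG = 0.38, f_CHH = 0.50
  correspond to genome-wide losses of 24%, 62% and 50% of CG, CHG and CHH
  methylation, the regime of a metabolic supply mutant that starves all
  methyltransferase pathways at once.
* ``pathway_knockout`` — targeted context (optionally compartment) drops to
  a residual baseline, the regime of a methyltransferase null (met1-, cmt3-,
  cmt2-, drm-like).

Every output is a pure function of the configuration including its seed;
per-stage random streams are derived from the global seed with fixed offsets
so adding a stage never perturbs earlier draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genome_context import CONTEXTS, Genome, enumerate_cytosines
from .genetics_stats import SegregationCounts
from .methylome import CALL_COLUMNS, sites_in_regions

COMPARTMENTS = ("peri_te", "arm_te", "pcg_body", "intergenic")

# per-stage random-stream offsets (SeedSequence spawn keys)
_STREAM_GENOME = 1
_STREAM_FEATURES = 2
_STREAM_TRUTH = 3
_STREAM_COUNTS = 4
_STREAM_F2 = 5


@dataclass
class GenomeParams:
    n_chroms: int = 1
    chrom_length_bp: int = 1_000_000
    gc: float = 0.36
    pericentromere_fraction: float = 0.25


@dataclass
class AnnotationParams:
    te_coverage_peri: float = 0.60
    te_coverage_arm: float = 0.05
    pcg_coverage_arm: float = 0.40
    te_length_range: tuple[int, int] = (500, 5000)
    pcg_length_range: tuple[int, int] = (1000, 4000)
    family_probs: dict[str, float] = field(
        default_factory=lambda: {
            "LTR/Gypsy": 0.30,
            "LTR/Copia": 0.15,
            "DNA/MuDR": 0.15,
            "RC/Helitron": 0.25,
            "LINE/L1": 0.15,
        }
    )


#: wild-type mean methylation per compartment x context, shaped like a plant
#: methylome: heavy TE methylation concentrated in pericentromeric
#: heterochromatin, CG-only gene-body methylation, near-zero background.
DEFAULT_METH_MEANS: dict[str, dict[str, float]] = {
    "peri_te": {"CG": 0.85, "CHG": 0.65, "CHH": 0.20},
    "arm_te": {"CG": 0.75, "CHG": 0.45, "CHH": 0.12},
    "pcg_body": {"CG": 0.20, "CHG": 0.02, "CHH": 0.01},
    "intergenic": {"CG": 0.05, "CHG": 0.02, "CHH": 0.01},
}

#: genome-wide per-context reductions of a metabolic supply mutant
DEFAULT_UNIFORM_FACTORS = {"CG": 0.76, "CHG": 0.38, "CHH": 0.50}


@dataclass
class MutantModel:
    model: str = "uniform_proportional"  # or "pathway_knockout"
    factors: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_UNIFORM_FACTORS)
    )
    knockout_contexts: tuple[str, ...] = ()
    knockout_compartments: tuple[str, ...] | None = None  # None = everywhere
    baseline: float = 0.01


def mutant_preset(name: str) -> MutantModel:
    """Canonical mutant models: the supply mutant and pathway knockouts."""
    presets = {
        "mthfd1": MutantModel(),
        "met1": MutantModel(model="pathway_knockout", knockout_contexts=("CG",)),
        "cmt3": MutantModel(model="pathway_knockout", knockout_contexts=("CHG",)),
        "cmt2": MutantModel(
            model="pathway_knockout",
            knockout_contexts=("CHH",),
            knockout_compartments=("peri_te",),
        ),
        "drm": MutantModel(
            model="pathway_knockout",
            knockout_contexts=("CHH",),
            knockout_compartments=("arm_te", "pcg_body", "intergenic"),
        ),
    }
    if name not in presets:
        raise ValueError(f"unknown mutant preset {name!r}")
    return presets[name]


@dataclass
class F2Params:
    n_plants: int = 400
    homozygote_viability: float = 1.0
    n_chroms: int = 2
    chrom_length_bp: int = 30_000_000
    causal_chrom: str = "chr1"
    causal_pos: int = 5_000_000
    marker_spacing_bp: int = 100_000
    cM_per_Mb: float = 4.0
    read_depth: float = 30.0


@dataclass
class SimConfig:
    seed: int = 0
    genome: GenomeParams = field(default_factory=GenomeParams)
    annotation: AnnotationParams = field(default_factory=AnnotationParams)
    meth_means: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_METH_MEANS.items()}
    )
    beta_concentration: float = 15.0
    depth: float = 30.0
    non_conversion: float = 0.005
    mutant: MutantModel = field(default_factory=MutantModel)
    f2: F2Params = field(default_factory=F2Params)

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if not 0 <= self.non_conversion < 0.05:
            raise ValueError("non_conversion must be in [0, 0.05)")
        for comp, ctx_means in self.meth_means.items():
            for ctx, mu in ctx_means.items():
                if not 0 <= mu <= 1:
                    raise ValueError(f"mean {comp}/{ctx}={mu} outside [0, 1]")


def _rng(cfg: SimConfig, stream: int, extra: int = 0) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stream, extra])


# ---------------------------------------------------------------------------
# genome


def simulate_genome(cfg: SimConfig) -> tuple[Genome, dict[str, tuple[int, int]]]:
    """Random genome plus a centered pericentromere interval per chromosome."""
    g = cfg.genome
    if g.chrom_length_bp < 10_000:
        raise ValueError("chromosomes must be at least 10 kb")
    if not 0 <= g.pericentromere_fraction <= 1:
        raise ValueError("pericentromere_fraction must be in [0, 1]")
    rng = _rng(cfg, _STREAM_GENOME)
    p_gc = g.gc / 2
    p_at = (1 - g.gc) / 2
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    chroms: dict[str, str] = {}
    compartments: dict[str, tuple[int, int]] = {}
    for i in range(g.n_chroms):
        name = f"chr{i + 1}"
        arr = rng.choice(bases, size=g.chrom_length_bp, p=[p_at, p_gc, p_gc, p_at])
        chroms[name] = arr.tobytes().decode("ascii")
        half = int(g.chrom_length_bp * g.pericentromere_fraction) // 2
        mid = g.chrom_length_bp // 2
        compartments[name] = (mid - half, mid + half)
    return Genome(chroms), compartments


# ---------------------------------------------------------------------------
# annotation


def _place_intervals(
    rng: np.random.Generator,
    region_start: int,
    region_end: int,
    coverage: float,
    length_range: tuple[int, int],
) -> list[tuple[int, int]]:
    """Sequentially place non-overlapping intervals at a target coverage.

    Gaps are exponential with mean chosen so the expected covered fraction
    equals ``coverage``.
    """
    if coverage <= 0:
        return []
    mean_len = sum(length_range) / 2
    mean_gap = mean_len * (1 - coverage) / coverage
    out = []
    pos = region_start
    while True:
        pos += int(rng.exponential(mean_gap)) if mean_gap > 0 else 0
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        if pos + length > region_end:
            break
        out.append((pos, pos + length))
        pos += length
    return out


def simulate_features(
    genome: Genome,
    compartments: dict[str, tuple[int, int]],
    cfg: SimConfig,
) -> pd.DataFrame:
    """TE and PCG annotation: TEs concentrated in the pericentromere, PCGs
    on the arms, random strands, TE families from the configured
    distribution. Features never overlap within a kind."""
    a = cfg.annotation
    rng = _rng(cfg, _STREAM_FEATURES)
    families = list(a.family_probs)
    fam_p = np.array([a.family_probs[f] for f in families])
    if not np.isclose(fam_p.sum(), 1.0):
        raise ValueError("family probabilities must sum to 1")
    rows = []
    te_i = pcg_i = 0
    for chrom, seq in genome.chromosomes.items():
        size = len(seq)
        peri_s, peri_e = compartments[chrom]
        te_spans = []
        for lo, hi, cov in (
            (0, peri_s, a.te_coverage_arm),
            (peri_s, peri_e, a.te_coverage_peri),
            (peri_e, size, a.te_coverage_arm),
        ):
            te_spans += _place_intervals(rng, lo, hi, cov, a.te_length_range)
        for s, e in te_spans:
            te_i += 1
            rows.append(
                {
                    "chrom": chrom,
                    "start": s,
                    "end": e,
                    "strand": "+" if rng.random() < 0.5 else "-",
                    "kind": "TE",
                    "family": families[rng.choice(len(families), p=fam_p)],
                    "name": f"TE{te_i:05d}",
                }
            )
        pcg_spans = []
        for lo, hi in ((0, peri_s), (peri_e, size)):
            pcg_spans += _place_intervals(
                rng, lo, hi, a.pcg_coverage_arm, a.pcg_length_range
            )
        for s, e in pcg_spans:
            pcg_i += 1
            rows.append(
                {
                    "chrom": chrom,
                    "start": s,
                    "end": e,
                    "strand": "+" if rng.random() < 0.5 else "-",
                    "kind": "PCG",
                    "family": "",
                    "name": f"GENE{pcg_i:05d}",
                }
            )
    features = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "strand", "kind", "family", "name"]
    )
    return features.sort_values(["chrom", "start"], kind="mergesort").reset_index(
        drop=True
    )


# ---------------------------------------------------------------------------
# true methylome


def assign_compartments(
    sites: pd.DataFrame,
    features: pd.DataFrame,
    compartments: dict[str, tuple[int, int]],
) -> pd.Series:
    """Compartment of each cytosine site; TE beats PCG where they overlap."""
    comp = pd.Series("intergenic", index=sites.index, dtype=object)
    in_peri = np.zeros(len(sites), dtype=bool)
    for chrom, (s, e) in compartments.items():
        sel = (sites["chrom"] == chrom).to_numpy()
        in_peri |= sel & (sites["pos"].to_numpy() >= s) & (sites["pos"].to_numpy() < e)
    pcgs = features[features["kind"] == "PCG"]
    if len(pcgs):
        comp[sites_in_regions(sites, pcgs)] = "pcg_body"
    tes = features[features["kind"] == "TE"]
    if len(tes):
        in_te = sites_in_regions(sites, tes)
        comp[in_te & in_peri] = "peri_te"
        comp[in_te & ~in_peri] = "arm_te"
    return comp


def simulate_true_methylome(
    sites: pd.DataFrame,
    features: pd.DataFrame,
    compartments: dict[str, tuple[int, int]],
    cfg: SimConfig,
) -> pd.DataFrame:
    """Latent per-site methylation probability.

    Each site's probability is beta-distributed around its compartment x
    context mean with the configured concentration (infinite concentration
    degenerates to the mean exactly).
    """
    truth = sites.copy()
    truth["compartment"] = assign_compartments(sites, features, compartments)
    rng = _rng(cfg, _STREAM_TRUTH)
    p = np.empty(len(truth))
    kappa = cfg.beta_concentration
    for comp in COMPARTMENTS:
        if comp not in cfg.meth_means:
            raise ValueError(f"missing methylation means for {comp!r}")
        for ctx in CONTEXTS:
            if ctx not in cfg.meth_means[comp]:
                raise ValueError(f"missing methylation mean for {comp}/{ctx}")
            mask = (
                (truth["compartment"] == comp) & (truth["context"] == ctx)
            ).to_numpy()
            n = int(mask.sum())
            if n == 0:
                continue
            mu = cfg.meth_means[comp][ctx]
            if not np.isfinite(kappa) or mu in (0.0, 1.0):
                p[mask] = mu
            else:
                p[mask] = rng.beta(mu * kappa, (1 - mu) * kappa, size=n)
    truth["p_true"] = p
    return truth


def apply_mutant_model(truth: pd.DataFrame, model: MutantModel) -> pd.DataFrame:
    """Derive a mutant true methylome from the wild-type one."""
    out = truth.copy()
    if model.model == "uniform_proportional":
        factors = out["context"].map(model.factors).astype(float).to_numpy()
        if np.isnan(factors).any():
            raise ValueError("uniform_proportional needs a factor per context")
        out["p_true"] = out["p_true"].to_numpy() * factors
    elif model.model == "pathway_knockout":
        mask = out["context"].isin(model.knockout_contexts).to_numpy()
        if model.knockout_compartments is not None:
            mask &= out["compartment"].isin(model.knockout_compartments).to_numpy()
        p = out["p_true"].to_numpy().copy()
        p[mask] = model.baseline
        out["p_true"] = p
    else:
        raise ValueError(f"unknown mutant model {model.model!r}")
    return out


# ---------------------------------------------------------------------------
# observed counts


def simulate_counts(
    truth: pd.DataFrame,
    cfg: SimConfig,
    depth: float | None = None,
    replicate: int = 0,
) -> pd.DataFrame:
    """Observed call table: Poisson coverage, binomial methylated-read counts.

    Coverage ~ Poisson(depth) per site; methylated reads ~ Binomial(coverage,
    p + (1 - p) * epsilon) where epsilon is the bisulfite non-conversion
    rate. ``replicate`` selects an independent random stream so several
    libraries can be drawn from one truth.
    """
    depth = cfg.depth if depth is None else depth
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = _rng(cfg, _STREAM_COUNTS, replicate)
    p = truth["p_true"].to_numpy()
    obs_p = p + (1.0 - p) * cfg.non_conversion
    coverage = rng.poisson(depth, size=len(truth))
    n_meth = rng.binomial(coverage, obs_p)
    calls = truth[["chrom", "pos", "strand", "context"]].copy()
    calls["n_meth"] = n_meth
    calls["n_unmeth"] = coverage - n_meth
    return calls[CALL_COLUMNS]


# ---------------------------------------------------------------------------
# full methylome pair


def simulate_methylome_pair(cfg: SimConfig) -> dict:
    """Genome, annotation, truths and observed call tables for WT + mutant."""
    genome, compartments = simulate_genome(cfg)
    features = simulate_features(genome, compartments, cfg)
    sites = enumerate_cytosines(genome)
    truth_wt = simulate_true_methylome(sites, features, compartments, cfg)
    truth_mut = apply_mutant_model(truth_wt, cfg.mutant)
    calls_wt = simulate_counts(truth_wt, cfg, replicate=0)
    calls_mut = simulate_counts(truth_mut, cfg, replicate=1)
    return {
        "genome": genome,
        "compartments": compartments,
        "features": features,
        "sites": sites,
        "truth_wt": truth_wt,
        "truth_mut": truth_mut,
        "calls_wt": calls_wt,
        "calls_mut": calls_mut,
    }


# ---------------------------------------------------------------------------
# F2 population: segregation counts and BSA marker table


def _haldane_r(dist_bp: np.ndarray, cM_per_Mb: float) -> np.ndarray:
    """Recombination fraction from physical distance via the Haldane map."""
    morgans = dist_bp / 1e6 * cM_per_Mb / 100.0
    return 0.5 * (1.0 - np.exp(-2.0 * morgans))


def simulate_f2(cfg: SimConfig) -> tuple[SegregationCounts, pd.DataFrame]:
    """F2 population from a mutant x mapping-parent cross.

    Each plant inherits two gametes; the causal genotype follows Mendelian
    1/4 : 1/2 : 1/4. A plant is phenotype-positive iff homozygous mutant and
    surviving (``homozygote_viability``). Segregation counts are
    (positive, negative) among surviving plants against 1:3. The bulk of
    positive plants yields a marker table: on the causal chromosome each
    gamete's marker allele recombines away from its causal allele with the
    Haldane fraction for the marker-locus distance; other chromosomes are
    unlinked. Marker read counts are binomial draws at Poisson depth from
    the bulk allele frequency.
    """
    f2 = cfg.f2
    if f2.n_plants < 1:
        raise ValueError("need at least one plant")
    rng = _rng(cfg, _STREAM_F2)
    n = f2.n_plants
    # one causal allele per gamete: 1 = mutant-parent allele
    g1 = rng.integers(0, 2, size=n)
    g2 = rng.integers(0, 2, size=n)
    hom_mut = (g1 == 1) & (g2 == 1)
    survives = np.ones(n, dtype=bool)
    if f2.homozygote_viability < 1.0:
        survives[hom_mut] = rng.random(int(hom_mut.sum())) < f2.homozygote_viability
    positive = hom_mut & survives
    n_pos = int(positive.sum())
    n_neg = int(survives.sum()) - n_pos
    seg = SegregationCounts(counts=(n_pos, n_neg), ratio=(1.0, 3.0))

    bulk1, bulk2 = g1[positive], g2[positive]
    n_bulk = n_pos
    rows = []
    for i in range(f2.n_chroms):
        chrom = f"chr{i + 1}"
        positions = np.arange(0, f2.chrom_length_bp + 1, f2.marker_spacing_bp)
        if n_bulk == 0:
            mut_alleles = np.zeros(len(positions))
        elif chrom == f2.causal_chrom:
            r = _haldane_r(np.abs(positions - f2.causal_pos), f2.cM_per_Mb)
            flip1 = rng.random((n_bulk, len(positions))) < r
            flip2 = rng.random((n_bulk, len(positions))) < r
            a1 = bulk1[:, None] ^ flip1
            a2 = bulk2[:, None] ^ flip2
            mut_alleles = (a1 + a2).sum(axis=0)
        else:
            a1 = rng.integers(0, 2, size=(n_bulk, len(positions)))
            a2 = rng.integers(0, 2, size=(n_bulk, len(positions)))
            mut_alleles = (a1 + a2).sum(axis=0)
        freq = mut_alleles / (2 * n_bulk) if n_bulk else np.zeros(len(positions))
        depth = rng.poisson(f2.read_depth, size=len(positions))
        n_mut = rng.binomial(depth, freq)
        rows.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": positions,
                    "n_mut_allele": n_mut,
                    "n_other_allele": depth - n_mut,
                }
            )
        )
    markers = pd.concat(rows, ignore_index=True)
    return seg, markers


def with_mutant(cfg: SimConfig, preset: str) -> SimConfig:
    """Copy of a config with the mutant model replaced by a preset."""
    return replace(cfg, mutant=mutant_preset(preset))
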