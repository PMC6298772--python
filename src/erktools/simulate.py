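"""Synthetic-data generators with planted ground truth.

Three generators emulate the three input families of the pipeline:

* a pooled CRISPR knockout screen — negative-binomial read counts around a
  lognormal-skewed plasmid library, with gene-level enrichment/depletion
  effects planted into the treated final population;
* a tumor expression cohort — lognormal RSEM-like expression for a panel of
  negative-feedback regulators, one gene up-regulated in mutation-positive
  samples, with an RPPA phospho-ERK marker linearly coupled to that gene;
* a dose-response plate — Hill-curve viability across a 17-point dose series
  read out as noisy fluorescence.

Every generator is a pure function of its spec (which includes the seed):
identical specs give identical outputs. Each generated table draws from its
own RNG stream derived from the master seed by stable named sub-seeding, so
adding a table never perturbs the others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (
    CONTROL_GENE,
    ExpressionTable,
    GuideLibrary,
    PlateReadings,
    RPPATable,
    SampleAnnotation,
    ScreenCountMatrix,
)

#: The 13 ERK-pathway negative-feedback regulators scanned by default:
#: the dual-specificity phosphatases, sprouty and sprouty-related families.
DEFAULT_PANEL = (
    "DUSP1", "DUSP2", "DUSP3", "DUSP4", "DUSP5", "DUSP6",
    "SPRED1", "SPRED2", "SPRED3",
    "SPRY1", "SPRY2", "SPRY3", "SPRY4",
)

#: RPPA marker ids: phospho-ERK (coupled), phospho-p38 and phospho-JNK (noise).
PERK_MARKER = "MAPKPT202Y204"
NOISE_MARKERS = ("P38PT180Y18", "JNKPT183Y185")

#: Default 17-point dose series: 0 to 8 µM in 0.5 µM increments.
DEFAULT_DOSES = tuple(np.round(np.arange(0.0, 8.01, 0.5), 3))


def sub_rng(seed: int, name: str) -> np.random.Generator:
    """RNG stream for table ``name`` derived stably from the master seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode())])
    )


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial counts with variance mean + dispersion * mean^2.

    dispersion == 0 degenerates to Poisson.
    """
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    size_param = 1.0 / dispersion
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p)


# ---------------------------------------------------------------------------
# CRISPR screen
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScreenSimSpec:
    """Conditions for a simulated knockout screen.

    planted_effects maps gene -> log2 effect on treated-final abundance
    (positive = enriched, negative = depleted); all other genes are null.
    """

    n_genes: int
    guides_per_gene: int = 4
    n_control_guides: int = 50
    mean_depth: float = 500.0
    nb_dispersion: float = 0.2
    planted_effects: dict[str, float] = field(default_factory=dict)
    guide_effect_jitter_sd: float = 0.25  # log2 units, exercises second-best ranking
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.guides_per_gene < 2:
            raise ValueError("guides_per_gene must be >= 2 (ranking needs a second guide)")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be > 0")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if len(self.planted_effects) > self.n_genes:
            raise ValueError("more planted effects than genes")


def simulate_screen(
    spec: ScreenSimSpec,
) -> tuple[GuideLibrary, ScreenCountMatrix, dict[str, float]]:
    """Simulate a screen with samples plasmid / untreated_final / treated_final.

    Guide abundances follow a lognormal(0, 1) library profile renormalized to
    proportions; counts are negative-binomial around depth x abundance.
    Planted effects multiply treated-final abundances by 2^effect for every
    guide of the gene, with per-guide jitter Normal(0, 0.25) in log2 space.
    The returned truth map is the planted-effects map verbatim.
    """
    rng = sub_rng(spec.seed, "screen_counts")

    genes = sorted(spec.planted_effects)
    genes += [f"GENE{i:05d}" for i in range(spec.n_genes - len(genes))]
    guide_rows = []
    for gene in genes:
        for j in range(spec.guides_per_gene):
            guide_rows.append((f"{gene}_sg{j + 1}", gene, False))
    for j in range(spec.n_control_guides):
        guide_rows.append((f"CTRL_sg{j + 1:03d}", CONTROL_GENE, True))
    lib_frame = pd.DataFrame(guide_rows, columns=["guide_id", "gene", "is_control"])
    lib_frame["sequence"] = ""
    library = GuideLibrary(lib_frame[["guide_id", "gene", "sequence", "is_control"]])

    n_guides = len(lib_frame)
    abundance = rng.lognormal(mean=0.0, sigma=1.0, size=n_guides)
    abundance /= abundance.sum()
    total_reads = spec.mean_depth * n_guides

    effect = np.zeros(n_guides)
    for gene, eff in spec.planted_effects.items():
        idx = (lib_frame["gene"] == gene).to_numpy()
        effect[idx] = eff + rng.normal(0.0, spec.guide_effect_jitter_sd, idx.sum())
    treated_abundance = abundance * np.exp2(effect)
    treated_abundance /= treated_abundance.sum()

    counts = pd.DataFrame(
        {
            "plasmid": _nb_draw(rng, total_reads * abundance, spec.nb_dispersion),
            "untreated_final": _nb_draw(rng, total_reads * abundance, spec.nb_dispersion),
            "treated_final": _nb_draw(rng, total_reads * treated_abundance, spec.nb_dispersion),
        },
        index=pd.Index(lib_frame["guide_id"], name="guide_id"),
    )
    matrix = ScreenCountMatrix(counts, reference_sample="plasmid")
    return library, matrix, dict(spec.planted_effects)


# ---------------------------------------------------------------------------
# expression cohort with RPPA coupling
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExpressionSimSpec:
    """Conditions for a simulated tumor cohort.

    Baseline expression is lognormal per gene (sd ``lognormal_sigma`` in log2
    units); ``effect_gene`` is multiplied by 2^log2_effect in mutant samples
    only. The phospho-ERK RPPA marker is slope x log2(effect_gene) + noise;
    two further markers are pure noise. Sample sizes default to the 107
    mutant vs 123 wild-type split of a 230-tumor cohort.
    """

    panel_genes: tuple[str, ...] = DEFAULT_PANEL
    n_mutant: int = 107
    n_wildtype: int = 123
    effect_gene: str = "DUSP6"
    log2_effect: float = 1.0
    lognormal_sigma: float = 0.5
    rppa_slope: float = 1.0
    rppa_noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.effect_gene not in self.panel_genes:
            raise ValueError(f"effect_gene {self.effect_gene!r} not in panel")
        if self.n_mutant < 2 or self.n_wildtype < 2:
            raise ValueError("need at least 2 samples per group")
        if self.lognormal_sigma <= 0:
            raise ValueError("lognormal_sigma must be > 0")


def simulate_expression_cohort(
    spec: ExpressionSimSpec,
) -> tuple[ExpressionTable, SampleAnnotation, RPPATable, dict]:
    """Simulate expression + mutation annotation + RPPA tables with known truth."""
    rng_expr = sub_rng(spec.seed, "cohort_expression")
    rng_rppa = sub_rng(spec.seed, "cohort_rppa")

    n = spec.n_mutant + spec.n_wildtype
    samples = [f"TUMOR{i + 1:04d}" for i in range(n)]
    mutant = np.zeros(n, dtype=bool)
    mutant[: spec.n_mutant] = True

    # per-gene baseline abundance on a realistic RSEM log2 scale
    base_log2 = rng_expr.uniform(6.0, 12.0, size=len(spec.panel_genes))
    log2_vals = base_log2[:, None] + rng_expr.normal(
        0.0, spec.lognormal_sigma, size=(len(spec.panel_genes), n)
    )
    gene_idx = list(spec.panel_genes).index(spec.effect_gene)
    log2_vals[gene_idx, mutant] += spec.log2_effect
    expr = ExpressionTable(
        pd.DataFrame(
            np.exp2(log2_vals),
            index=pd.Index(spec.panel_genes, name="gene"),
            columns=samples,
        )
    )

    flags = pd.DataFrame(
        False,
        index=pd.Index(samples, name="sample_id"),
        columns=["EGFR", "KRAS", "MET", "ERBB2", "BRAF", "NF1", "NRAS", "HRAS"],
    )
    # alternate the driving lesion between the two common drivers
    flags.loc[np.array(samples)[mutant][0::2], "KRAS"] = True
    flags.loc[np.array(samples)[mutant][1::2], "EGFR"] = True
    flags["tissue"] = "tumor"
    annot = SampleAnnotation(flags)

    perk = spec.rppa_slope * log2_vals[gene_idx] + rng_rppa.normal(
        0.0, spec.rppa_noise_sd, size=n
    )
    rppa = RPPATable(
        pd.DataFrame(
            [perk] + [rng_rppa.normal(0.0, 1.0, size=n) for _ in NOISE_MARKERS],
            index=pd.Index([PERK_MARKER, *NOISE_MARKERS], name="marker"),
            columns=samples,
        )
    )

    truth = {
        "effect_gene": spec.effect_gene,
        "log2_effect": spec.log2_effect,
        "rppa_slope": spec.rppa_slope,
        "rppa_noise_sd": spec.rppa_noise_sd,
    }
    return expr, annot, rppa, truth


# ---------------------------------------------------------------------------
# dose-response plates
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CellLineSpec:
    name: str
    true_ic50: float  # µM
    hill: float
    floor: float  # residual viability fraction at saturating dose

    def __post_init__(self) -> None:
        if self.true_ic50 <= 0 or self.hill <= 0:
            raise ValueError("ic50 and hill must be > 0")
        if not 0.0 <= self.floor < 1.0:
            raise ValueError("floor must be in [0, 1)")


#: Default simulated lines spanning the three sensitivity phenotypes:
#: a steeply responding line losing >90% viability by 3.2 µM, an
#: intermediate line, and a shallow high-floor insensitive line.
DEFAULT_CELL_LINES = (
    CellLineSpec("SIM-SENS", true_ic50=2.0, hill=6.0, floor=0.02),
    CellLineSpec("SIM-INTER", true_ic50=4.5, hill=3.0, floor=0.05),
    CellLineSpec("SIM-INSENS", true_ic50=6.0, hill=3.0, floor=0.40),
)


@dataclass(frozen=True)
class DoseSimSpec:
    """Conditions for a simulated BCI-style dose-response experiment."""

    cell_lines: tuple[CellLineSpec, ...] = DEFAULT_CELL_LINES
    doses: tuple[float, ...] = DEFAULT_DOSES
    replicates: int = 4
    noise_cv: float = 0.05
    baseline_signal: float = 10000.0
    seed: int = 0

    def __post_init__(self) -> None:
        doses = np.asarray(self.doses, dtype=float)
        if doses[0] != 0.0 or np.any(np.diff(doses) <= 0):
            raise ValueError("doses must be ascending and start at 0 (vehicle)")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")


def hill_viability(dose, ic50: float, hill: float, floor: float = 0.0):
    """Noise-free viability fraction v(d) = floor + (1-floor)/(1 + (d/ic50)^hill).

    v(0) = 1 exactly for any parameters.
    """
    dose = np.asarray(dose, dtype=float)
    return floor + (1.0 - floor) / (1.0 + (dose / ic50) ** hill)


def simulate_dose_response(spec: DoseSimSpec) -> PlateReadings:
    """Simulate plate-reader signals across the dose series for each line."""
    rng = sub_rng(spec.seed, "dose_response")
    rows = []
    for line in spec.cell_lines:
        v = hill_viability(spec.doses, line.true_ic50, line.hill, line.floor)
        for dose, vi in zip(spec.doses, v):
            noise = rng.normal(0.0, spec.noise_cv, size=spec.replicates)
            for rep in range(spec.replicates):
                rows.append(
                    (
                        line.name,
                        "BCI",
                        float(dose),
                        rep + 1,
                        vi * spec.baseline_signal * (1.0 + noise[rep]),
                    )
                )
    frame = pd.DataFrame(
        rows, columns=["cell_line", "condition", "dose", "replicate", "signal"]
    )
    return PlateReadings(frame)
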