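import numpy as np
import pandas as pd
import pytest

from erktools.io import GuideLibrary, ScreenCountMatrix


@pytest.fixture
def small_library() -> GuideLibrary:
    frame = pd.DataFrame(
        {
            "guide_id": ["A_sg1", "A_sg2", "A_sg3", "B_sg1", "B_sg2", "CTRL_sg1"],
            "gene": ["A", "A", "A", "B", "B", "CONTROL"],
            "sequence": [""] * 6,
            "is_control": [False] * 5 + [True],
        }
    )
    return GuideLibrary(frame)


@pytest.fixture
def small_counts(small_library) -> ScreenCountMatrix:
    counts = pd.DataFrame(
        {
            "plasmid": [100, 200, 50, 400, 80, 120],
            "treated_final": [800, 900, 40, 100, 35, 110],
        },
        index=pd.Index(small_library.frame["guide_id"], name="guide_id"),
    )
    return ScreenCountMatrix(counts, reference_sample="plasmid")


def screen_oracle(raw: pd.DataFrame, gene_of: dict, sample: str, reference: str,
                  threshold: int = 30, pseudocount: float = 1.0):
    """Independent direct transcription of the four screen-scoring formulas.

    Naive loops, no shared code with erktools.screen: reads-per-million per
    column, >= threshold raw reads in both compared columns, pseudocounted
    log2 ratio, and per-gene second-largest / second-smallest LFC with
    descending/ascending ranks tie-broken on gene label.
    """
    import math

    rpm = {}
    for col in raw.columns:
        total = sum(raw[col])
        rpm[col] = {g: raw.loc[g, col] * 1e6 / total for g in raw.index}
    lfcs = {}
    for g in raw.index:
        if raw.loc[g, sample] >= threshold and raw.loc[g, reference] >= threshold:
            lfcs[g] = math.log2(
                (rpm[sample][g] + pseudocount) / (rpm[reference][g] + pseudocount)
            )
    per_gene: dict[str, list] = {}
    for g, lfc in lfcs.items():
        per_gene.setdefault(gene_of[g], []).append(lfc)
    stats = {}
    for gene, vals in per_gene.items():
        if len(vals) >= 2:
            vals = sorted(vals)
            stats[gene] = (vals[-2], vals[1])
    ranked = [g for g in stats if gene_of.get(g) != "CONTROL" and g != "CONTROL"]
    enr = sorted(ranked, key=lambda g: (-stats[g][0], g))
    dep = sorted(ranked, key=lambda g: (stats[g][1], g))
    return (
        lfcs,
        stats,
        {g: i + 1 for i, g in enumerate(enr)},
        {g: i + 1 for i, g in enumerate(dep)},
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260919)
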