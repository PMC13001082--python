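"""Sample-level chemodiversity profiling of assigned formula matrices.

A study is represented as an :class:`IntensityMatrix` — a samples x
formulas relative-abundance table (pandas DataFrame with canonical
formula-string columns) plus a metadata table (fraction, source,
origin per sample). On top of it this module provides the standard
chemometric summaries: TIC normalization, heteroatom / compound-class
proportions, intensity-weighted mean descriptors, Ward.D2 hierarchical
clustering, PCA, and quadrant-based extraction of the formulas driving
each sample group in loading space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .formula import descriptors
from .io import parse_formula

__all__ = [
    "IntensityMatrix",
    "PcaResult",
    "HcaResult",
    "tic_normalize",
    "class_proportions",
    "weighted_descriptors",
    "hca_ward2",
    "pca",
    "quadrant_signatures",
]

FRACTIONS = ("HA", "FA", "NOM")
ORIGINS = ("terrestrial", "aquatic")


@dataclass
class IntensityMatrix:
    """Samples x formulas abundance table with per-sample metadata.

    ``values``: DataFrame, index = sample ids, columns = canonical
    formula strings, entries >= 0 (absent formulas are 0).
    ``meta``: DataFrame indexed like ``values`` with columns
    ``fraction``, ``source``, ``origin`` (extra columns are carried
    along untouched).
    """

    values: pd.DataFrame
    meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError("intensity matrix contains negative values")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate formula columns")
        if not self.meta.empty:
            self.meta = self.meta.reindex(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    @property
    def formulas(self) -> list[str]:
        return list(self.values.columns)

    def descriptor_table(self) -> pd.DataFrame:
        """Per-formula descriptor table (H/C, O/C, DBE, AI_mod, classes, mass)."""
        rows = []
        for f in self.values.columns:
            d = descriptors(parse_formula(f))
            rows.append(
                {
                    "formula": f,
                    "h_c": d.h_c,
                    "o_c": d.o_c,
                    "dbe": d.dbe,
                    "ai_mod": d.ai_mod,
                    "neutral_mass": d.neutral_mass,
                    "heteroatom_class": d.heteroatom_class,
                    "compound_class": d.compound_class,
                }
            )
        return pd.DataFrame(rows).set_index("formula")


@dataclass
class PcaResult:
    scores: pd.DataFrame        # samples x components
    loadings: pd.DataFrame      # features x components
    variance_explained: np.ndarray

    def component(self, k: int) -> str:
        name = f"PC{k}"
        if name not in self.loadings.columns:
            raise KeyError(f"unknown component {name}")
        return name


@dataclass
class HcaResult:
    linkage: np.ndarray         # scipy condensed merge tree, n-1 rows
    labels: pd.Index

    def cut(self, k: int) -> pd.Series:
        """Flat cluster assignment at ``k`` clusters (labels 1..k)."""
        assign = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return pd.Series(assign, index=self.labels, name="cluster")

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]


def tic_normalize(m: IntensityMatrix) -> IntensityMatrix:
    """Divide each sample row by its total intensity (row sums become 1)."""
    totals = m.values.sum(axis=1)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"samples with zero total intensity: {bad}")
    return IntensityMatrix(values=m.values.div(totals, axis=0), meta=m.meta)


def class_proportions(
    m: IntensityMatrix, by: str = "heteroatom", weighting: str = "intensity"
) -> pd.DataFrame:
    """Per-sample class proportions (rows sum to 1).

    ``by``: 'heteroatom' (CHO/CHNO/CHOS/CHNOS) or 'compound_class';
    ``weighting``: 'count' (each present formula counts once) or
    'intensity' (abundance-weighted).
    """
    if by not in {"heteroatom", "compound_class"}:
        raise ValueError(f"unknown grouping {by!r}")
    if weighting not in {"count", "intensity"}:
        raise ValueError(f"unknown weighting {weighting!r}")
    desc = m.descriptor_table()
    key = "heteroatom_class" if by == "heteroatom" else "compound_class"
    groups = desc[key]
    weights = m.values if weighting == "intensity" else (m.values > 0).astype(float)
    totals = weights.sum(axis=1)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"samples with no assigned formulas: {bad}")
    agg = weights.T.groupby(groups).sum().T
    return agg.div(totals, axis=0)


def weighted_descriptors(m: IntensityMatrix) -> pd.DataFrame:
    """Intensity-weighted mean H/C, O/C and DBE per sample."""
    desc = m.descriptor_table()
    totals = m.values.sum(axis=1)
    if (totals <= 0).any():
        raise ValueError("sample with zero total intensity")
    out = {}
    for col in ("h_c", "o_c", "dbe"):
        out[col] = (m.values * desc[col].to_numpy()).sum(axis=1) / totals
    return pd.DataFrame(out)


def hca_ward2(values: pd.DataFrame) -> HcaResult:
    """Agglomerative clustering, Ward.D2 criterion on Euclidean distances.

    Heights follow the square-root (Ward.D2) convention: the merge
    height is the Euclidean-scale Ward distance, so two identical rows
    merge at 0 and heights are non-decreasing.
    """
    if len(values) < 2:
        raise ValueError("clustering requires at least 2 samples")
    z = hierarchy.linkage(pdist(values.to_numpy(), metric="euclidean"), method="ward")
    return HcaResult(linkage=z, labels=values.index)


def pca(values: pd.DataFrame, center: bool = True, scale: bool = True) -> PcaResult:
    """PCA by SVD of the (optionally centered/standardized) data matrix.

    Loadings are the orthonormal right singular vectors; scores are the
    projections of the processed data. The sign of each component is
    fixed so that its largest-magnitude loading entry is positive.
    """
    if len(values) < 2:
        raise ValueError("PCA requires at least 2 samples")
    x = values.to_numpy(dtype=float).copy()
    if center:
        x -= x.mean(axis=0)
    if scale:
        sd = x.std(axis=0, ddof=1)
        if (sd == 0).any():
            raise ValueError("constant column(s) present with scale=True")
        x /= sd
    u, sv, vt = np.linalg.svd(x, full_matrices=False)
    # deterministic sign: largest-|loading| entry positive per component
    for j in range(vt.shape[0]):
        i = np.argmax(np.abs(vt[j]))
        if vt[j, i] < 0:
            vt[j] *= -1
            u[:, j] *= -1
    ncomp = len(sv)
    names = [f"PC{k + 1}" for k in range(ncomp)]
    var = sv**2
    scores = pd.DataFrame(u * sv, index=values.index, columns=names)
    loadings = pd.DataFrame(vt.T, index=values.columns, columns=names)
    return PcaResult(scores=scores, loadings=loadings,
                     variance_explained=var / var.sum())


def quadrant_signatures(
    p: PcaResult, group_rules: dict[str, dict[str, int]]
) -> dict[str, list[str]]:
    """Formulas whose loading signs match each group's quadrant rule.

    ``group_rules`` maps a group name to a sign pattern over components,
    e.g. ``{"terrestrial_HA": {"PC1": -1}, "PLFA": {"PC1": +1, "PC3": +1}}``.
    Sign matching is strict: a zero loading on a ruled component excludes
    the formula.
    """
    out: dict[str, list[str]] = {}
    for group, rule in group_rules.items():
        mask = np.ones(len(p.loadings), dtype=bool)
        for comp, sign in rule.items():
            if comp not in p.loadings.columns:
                raise KeyError(f"unknown component {comp!r}")
            col = p.loadings[comp].to_numpy()
            mask &= (col > 0) if sign > 0 else (col < 0)
        out[group] = list(p.loadings.index[mask])
    return out
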