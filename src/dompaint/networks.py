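"""Mass-difference networks and Kendrick-mass-defect analysis.

Selected molecular formulas are linked into an undirected network when
their composition (or exact-mass) difference matches an entry of a
transformation table — a curated list of common functional-group and
structural modifications observed in natural organic matter (alkyl
chain extension, carbon addition, acylation, carbonylation, oxidation,
hydroxylation/hydration, carboxylation, amino-related transformations,
diazomethylation). Connected components ("subnetworks") and the
frequency ranking of transformations summarize the dominant chemistry.

Kendrick mass defect (KMD) analysis rescales masses so that members of
a homologous series (repeating CH2 or O units) share a common defect,
allowing series detection by simple grouping.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .constants import MASS_CH2, MASS_O
from .formula import ElementVector, exact_mass
from .io import formula_string

__all__ = [
    "Transformation",
    "TransformationTable",
    "default_transformation_table",
    "KendrickPoint",
    "build_network",
    "subnetworks_and_frequencies",
    "kendrick_transform",
    "kmd_series",
    "KENDRICK_BASES",
]

KENDRICK_BASES = {"CH2": MASS_CH2, "O": MASS_O}


@dataclass(frozen=True)
class Transformation:
    """A mass/composition difference with its chemical interpretation."""

    label: str
    delta: dict[str, int]       # signed element counts, keys chnos
    category: str

    @property
    def mass_delta(self) -> float:
        return exact_mass(self.delta)


@dataclass
class TransformationTable:
    entries: list[Transformation]

    def __post_init__(self) -> None:
        for t in self.entries:
            if abs(t.mass_delta - exact_mass(t.delta)) > 1e-9:
                raise ValueError(f"inconsistent mass delta for {t.label}")

    def __len__(self) -> int:
        return len(self.entries)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": [t.label for t in self.entries],
                "dc": [t.delta.get("c", 0) for t in self.entries],
                "dh": [t.delta.get("h", 0) for t in self.entries],
                "dn": [t.delta.get("n", 0) for t in self.entries],
                "do": [t.delta.get("o", 0) for t in self.entries],
                "ds": [t.delta.get("s", 0) for t in self.entries],
                "category": [t.category for t in self.entries],
                "mass_delta": [t.mass_delta for t in self.entries],
            }
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "TransformationTable":
        df = pd.read_csv(path, comment="#")
        req = {"label", "dc", "dh", "dn", "do", "ds", "category"}
        missing = req - set(df.columns)
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        entries = [
            Transformation(
                label=r["label"],
                delta={"c": int(r["dc"]), "h": int(r["dh"]), "n": int(r["dn"]),
                       "o": int(r["do"]), "s": int(r["ds"])},
                category=r["category"],
            )
            for _, r in df.iterrows()
        ]
        return cls(entries=entries)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _t(label: str, category: str, **delta: int) -> Transformation:
    full = {el: delta.get(el, 0) for el in "chnos"}
    return Transformation(label=label, delta=full, category=category)


def default_transformation_table() -> TransformationTable:
    """The packaged 40-entry transformation table.

    Composed from the standard categories of organic-matter reaction
    chemistry; every delta keeps the hydrogen/nitrogen parity needed to
    connect two even-electron CHNOS neutrals. Replaceable via CSV.
    """
    e = [
        # alkyl chain extension
        _t("CH2", "alkylation", c=1, h=2),
        _t("C2H4", "alkylation", c=2, h=4),
        _t("C3H6", "alkylation", c=3, h=6),
        _t("C4H8", "alkylation", c=4, h=8),
        _t("C5H10", "alkylation", c=5, h=10),
        _t("C6H12", "alkylation", c=6, h=12),
        _t("C7H14", "alkylation", c=7, h=14),
        _t("C8H16", "alkylation", c=8, h=16),
        # skeletal carbon addition (ring growth / condensation)
        _t("C", "carbon_addition", c=1),
        _t("C2", "carbon_addition", c=2),
        _t("C3", "carbon_addition", c=3),
        _t("C4", "carbon_addition", c=4),
        _t("C2H2", "carbon_addition", c=2, h=2),
        _t("C4H2", "carbon_addition", c=4, h=2),
        # acylation
        _t("C2H2O", "acylation", c=2, h=2, o=1),
        _t("C3H4O", "acylation", c=3, h=4, o=1),
        _t("C4H6O", "acylation", c=4, h=6, o=1),
        _t("C5H8O", "acylation", c=5, h=8, o=1),
        # carbonylation
        _t("CO", "carbonylation", c=1, o=1),
        _t("CH2O", "carbonylation", c=1, h=2, o=1),
        _t("C2H4O", "carbonylation", c=2, h=4, o=1),
        # oxidation / redox
        _t("O", "oxidation", o=1),
        _t("O2", "oxidation", o=2),
        _t("O3", "oxidation", o=3),
        _t("O4", "oxidation", o=4),
        _t("H2", "oxidation", h=2),            # (de)hydrogenation
        _t("O-H2", "oxidation", o=1, h=-2),    # carbonyl formation
        _t("O2-H2", "oxidation", o=2, h=-2),
        # hydroxylation / hydration
        _t("H2O", "hydroxylation", h=2, o=1),
        _t("H2O2", "hydroxylation", h=2, o=2),
        # carboxylation
        _t("CO2", "carboxylation", c=1, o=2),
        _t("CH2O2", "carboxylation", c=1, h=2, o=2),
        _t("C2H2O2", "carboxylation", c=2, h=2, o=2),
        # amino-related
        _t("NH", "amino", n=1, h=1),
        _t("NH3", "amino", n=1, h=3),
        _t("CH3N", "amino", c=1, h=3, n=1),
        _t("C2H5N", "amino", c=2, h=5, n=1),
        _t("NO2-H", "amino", n=1, o=2, h=-1),  # nitration
        _t("NO-H", "amino", n=1, o=1, h=-1),   # nitrosation
        # diazomethylation
        _t("CH2N2", "diazomethylation", c=1, h=2, n=2),
    ]
    table = TransformationTable(entries=e)
    assert len(table) == 40
    return table


@dataclass(frozen=True)
class KendrickPoint:
    """Kendrick mass, nominal Kendrick mass and defect for one base unit."""

    km: float
    nkm: int
    kmd: float
    base: str


def _node_key(f) -> str:
    return formula_string(f) if isinstance(f, ElementVector) else str(f)


def build_network(
    formulas: list[ElementVector],
    table: TransformationTable | None = None,
    mode: str = "elemental",
    tol_da: float = 0.0005,
) -> nx.Graph:
    """Link formulas whose pairwise differences match the table.

    ``mode='elemental'``: an edge (i, j) labeled t exists iff
    composition(j) - composition(i) equals +/- delta(t) exactly.
    ``mode='mass'``: iff ||m_i - m_j| - mass_delta(t)| <= tol_da.
    Multiple matching transformations become parallel labels on one
    edge; self-edges never occur.
    """
    if len(formulas) < 2:
        raise ValueError("need at least 2 formulas")
    if table is None:
        table = default_transformation_table()
    if mode not in {"elemental", "mass"}:
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "mass" and tol_da <= 0:
        raise ValueError("tol_da must be positive in mass mode")

    g = nx.Graph()
    keys = [_node_key(f) for f in formulas]
    masses = [exact_mass(f) for f in formulas]
    for k, f, m in zip(keys, formulas, masses):
        g.add_node(k, formula=f, mass=m)

    if mode == "elemental":
        lookup = {
            tuple(t.delta.get(el, 0) for el in "chnos"): t for t in table.entries
        }
        comp = {k: np.array(f.as_tuple()) for k, f in zip(keys, formulas)}
        for i in range(len(keys)):
            for j in range(i + 1, len(keys)):
                d = comp[keys[j]] - comp[keys[i]]
                labels = []
                for sign in (1, -1):
                    t = lookup.get(tuple(int(v) for v in sign * d))
                    if t is not None:
                        labels.append(t.label)
                if labels:
                    _add_edge(g, keys[i], keys[j], sorted(set(labels)),
                              abs(masses[j] - masses[i]))
    else:
        deltas = [(t.label, abs(t.mass_delta)) for t in table.entries]
        for i in range(len(keys)):
            for j in range(i + 1, len(keys)):
                dm = abs(masses[i] - masses[j])
                labels = [lab for lab, md in deltas if abs(dm - md) <= tol_da]
                if labels:
                    _add_edge(g, keys[i], keys[j], sorted(set(labels)), dm)
    return g


def _add_edge(g: nx.Graph, a: str, b: str, labels: list[str], dm: float) -> None:
    if a == b:
        return
    g.add_edge(a, b, labels=labels, delta_mass=dm)


def subnetworks_and_frequencies(
    net: nx.Graph, top_k: int = 20
) -> tuple[list[set[str]], pd.DataFrame]:
    """Connected components (largest first) and transformation frequency ranking.

    Frequency counts each edge once per matching label; the ranking is
    by count (descending) with ties broken toward the smaller mass
    delta, truncated to ``top_k`` rows.
    """
    components = sorted(nx.connected_components(net), key=len, reverse=True)
    counts: dict[str, int] = {}
    mass_by_label: dict[str, float] = {}
    for _, _, data in net.edges(data=True):
        for lab in data["labels"]:
            counts[lab] = counts.get(lab, 0) + 1
            mass_by_label.setdefault(lab, data["delta_mass"])
    rows = [
        {"label": lab, "count": cnt, "mass_delta": mass_by_label.get(lab, np.nan)}
        for lab, cnt in counts.items()
    ]
    df = pd.DataFrame(rows, columns=["label", "count", "mass_delta"])
    if not df.empty:
        df = df.sort_values(
            ["count", "mass_delta", "label"], ascending=[False, True, True]
        ).head(top_k).reset_index(drop=True)
    return components, df


def kendrick_transform(mass: float, base: str = "CH2") -> KendrickPoint:
    """Kendrick mass, nominal Kendrick mass and mass defect.

    km = mass * round(M_base) / M_base; nkm = round(km); kmd = nkm - km.
    Members of a homologous series in the base unit share kmd exactly.
    """
    if not mass > 0:
        raise ValueError("mass must be positive")
    if base not in KENDRICK_BASES:
        raise ValueError(f"unknown Kendrick base {base!r}")
    m_base = KENDRICK_BASES[base]
    km = mass * round(m_base) / m_base
    nkm = int(round(km))
    return KendrickPoint(km=km, nkm=nkm, kmd=nkm - km, base=base)


def kmd_series(
    formulas: list[ElementVector],
    base: str = "CH2",
    kmd_tol: float = 5e-4,
    min_size: int = 2,
) -> list[list[str]]:
    """Detect homologous series sharing a Kendrick mass defect.

    Formulas whose KMD agree within ``kmd_tol`` and whose masses differ
    by integer multiples of the base-unit mass (within 2 * kmd_tol per
    step check) form one series; series smaller than ``min_size`` are
    discarded. Each formula joins at most one series per base.
    """
    m_base = KENDRICK_BASES[base]
    items = sorted(
        (
            (exact_mass(f), kendrick_transform(exact_mass(f), base).kmd, _node_key(f))
            for f in formulas
        ),
        key=lambda t: t[0],
    )
    assigned: set[str] = set()
    series: list[list[str]] = []
    for i, (m_i, kmd_i, key_i) in enumerate(items):
        if key_i in assigned:
            continue
        grp = [(m_i, key_i)]
        for m_j, kmd_j, key_j in items[i + 1:]:
            if key_j in assigned:
                continue
            if abs(kmd_j - kmd_i) > kmd_tol:
                continue
            steps = (m_j - m_i) / m_base
            if abs(steps - round(steps)) * m_base <= 2 * kmd_tol and round(steps) >= 1:
                grp.append((m_j, key_j))
        if len(grp) >= min_size:
            members = [k for _, k in grp]
            assigned.update(members)
            series.append(members)
    return series


def write_edge_list(net: nx.Graph, path: str | Path) -> None:
    rows = [
        {"source": a, "target": b, "label": ";".join(d["labels"]),
         "delta_mass": d["delta_mass"]}
        for a, b, d in net.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["source", "target", "label", "delta_mass"]).to_csv(
        path, index=False
    )


def write_graphml(net: nx.Graph, path: str | Path) -> None:
    g = net.copy()
    for _, _, d in g.edges(data=True):
        d["labels"] = ";".join(d["labels"])
    for _, d in g.nodes(data=True):
        d.pop("formula", None)  # ElementVector is not GraphML-serializable
    nx.write_graphml(g, path)
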