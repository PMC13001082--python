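"""Molecular formula assignment and descriptors for CHNOS compositions.

Calibrated negative-mode (ESI(-), [M-H]-) peak lists are translated into
neutral CHNOS molecular formulas by exhaustive search over a bounded
composition lattice, then annotated with the van Krevelen descriptors
(H/C, O/C), double bond equivalents (DBE), the modified aromaticity
index (AI_mod) and the standard four-way compound classification used
for dissolved organic matter:

* highly unsaturated / phenolic:  AI_mod <= 0.5 and H/C < 1.5
* aromatic:                       0.5 < AI_mod <= 0.67
* polycyclic aromatic:            AI_mod > 0.67
* aliphatic:                      AI_mod <= 0.5 and H/C >= 1.5

All species are assumed to be singly charged deprotonated even-electron
neutrals; candidates with negative or non-integer DBE are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import (
    ELEMENT_MASSES,
    MASS_C,
    MASS_H,
    MASS_N,
    MASS_O,
    MASS_PROTON,
    MASS_S,
)

__all__ = [
    "ElementVector",
    "Peak",
    "DescriptorSet",
    "AssignmentConfig",
    "FormulaRecord",
    "exact_mass",
    "mz_to_neutral",
    "assign_formulas",
    "descriptors",
    "classify_compound",
    "COMPOUND_CLASSES",
    "HETEROATOM_CLASSES",
]

COMPOUND_CLASSES = (
    "highly_unsaturated_phenolic",
    "aromatic",
    "polycyclic_aromatic",
    "aliphatic",
)
HETEROATOM_CLASSES = ("CHO", "CHNO", "CHOS", "CHNOS")


@dataclass(frozen=True, order=True)
class ElementVector:
    """Integer C/H/N/O/S composition of a neutral formula (P fixed at 0)."""

    c: int
    h: int
    n: int = 0
    o: int = 0
    s: int = 0

    def __post_init__(self) -> None:
        for name in ("c", "h", "n", "o", "s"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"element count {name}={v!r} must be a non-negative integer")
        if self.c < 1:
            raise ValueError("assigned formulas require at least one carbon")
        if self.h < 1:
            raise ValueError("assigned formulas require at least one hydrogen")

    def __add__(self, other: "ElementVector") -> "ElementVector":
        return ElementVector(
            self.c + other.c, self.h + other.h, self.n + other.n,
            self.o + other.o, self.s + other.s,
        )

    def as_tuple(self) -> tuple[int, int, int, int, int]:
        return (self.c, self.h, self.n, self.o, self.s)


@dataclass(frozen=True)
class Peak:
    """A calibrated singly charged mass peak: m/z (Da) and relative abundance."""

    mz: float
    intensity: float

    def __post_init__(self) -> None:
        if not self.mz > 0:
            raise ValueError(f"m/z must be positive, got {self.mz}")
        if self.intensity < 0:
            raise ValueError(f"intensity must be non-negative, got {self.intensity}")


@dataclass(frozen=True)
class DescriptorSet:
    h_c: float
    o_c: float
    dbe: float
    ai_mod: float
    neutral_mass: float
    heteroatom_class: str
    compound_class: str


@dataclass
class AssignmentConfig:
    """Search-space and filter settings for formula assignment.

    Defaults follow common negative-mode FT-ICR practice for natural
    organic matter: sub-ppm tolerance, generous CHNOS bounds, elemental
    ratio windows and the even-electron (integer DBE >= 0) rule.
    """

    tolerance_ppm: float = 0.5
    bounds: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {
            "c": (1, 100),
            "h": (1, 200),
            "n": (0, 4),
            "o": (0, 80),
            "s": (0, 2),
        }
    )
    hc_range: tuple[float, float] = (0.3, 2.5)
    oc_range: tuple[float, float] = (0.0, 1.2)
    require_integer_nonneg_dbe: bool = True

    def validate(self) -> None:
        if not self.tolerance_ppm > 0:
            raise ValueError("tolerance_ppm must be positive")
        if not self.bounds:
            raise ValueError("element bounds must be non-empty")
        for el in ("c", "h", "n", "o", "s"):
            lo, hi = self.bounds.get(el, (0, 0))
            if lo < 0 or hi < lo:
                raise ValueError(f"invalid bounds for {el}: ({lo}, {hi})")
        if self.bounds["c"][1] < 1 or self.bounds["h"][1] < 1:
            raise ValueError("bounds must allow at least one C and one H")


@dataclass
class FormulaRecord:
    """Assignment result for one peak.

    ``candidates`` holds every composition surviving the filters, sorted
    by |ppm error|; ``primary`` is the lowest-error candidate or None for
    unassigned peaks.
    """

    peak: Peak
    candidates: list[tuple[ElementVector, float]]  # (formula, ppm error)

    @property
    def primary(self) -> ElementVector | None:
        return self.candidates[0][0] if self.candidates else None

    @property
    def primary_ppm_error(self) -> float | None:
        return self.candidates[0][1] if self.candidates else None

    @property
    def descriptors(self) -> DescriptorSet | None:
        ev = self.primary
        return None if ev is None else descriptors(ev)


def exact_mass(ev: ElementVector | dict[str, int]) -> float:
    """Neutral monoisotopic mass (Da) of a composition.

    Accepts an :class:`ElementVector` or a plain ``{element: count}``
    mapping (counts may be negative for transformation deltas).
    """
    if isinstance(ev, ElementVector):
        counts = dict(zip("chnos", ev.as_tuple()))
    else:
        counts = ev
    return float(sum(ELEMENT_MASSES[el] * int(cnt) for el, cnt in counts.items()))


def mz_to_neutral(mz: float) -> float:
    """Neutral mass of the [M-H]- ion observed at ``mz``."""
    if not mz > 0:
        raise ValueError(f"m/z must be positive, got {mz}")
    return mz + MASS_PROTON


def dbe_value(c: int, h: int, n: int) -> float:
    """Double bond equivalents of a neutral CcHhNnOoSs formula."""
    return 1.0 + c - h / 2.0 + n / 2.0


def ai_mod_value(c: int, h: int, n: int, o: int, s: int) -> float:
    """Modified aromaticity index with 0.5*O weighting and P = 0.

    Clamped to 0 when either the DBE_AI numerator or the carbon
    denominator is non-positive (the convention of the index's authors).
    """
    num = 1.0 + c - 0.5 * o - s - 0.5 * h
    den = c - 0.5 * o - s - n
    if num <= 0 or den <= 0:
        return 0.0
    return num / den


def heteroatom_class(n: int, s: int) -> str:
    if n > 0 and s > 0:
        return "CHNOS"
    if n > 0:
        return "CHNO"
    if s > 0:
        return "CHOS"
    return "CHO"


def classify_compound(ai_mod: float, h_c: float) -> str:
    """Four-way van Krevelen compound class from (AI_mod, H/C).

    The four predicates partition the plane: exactly one fires for any
    valid descriptor pair.
    """
    if ai_mod > 0.67:
        return "polycyclic_aromatic"
    if ai_mod > 0.5:
        return "aromatic"
    # ai_mod <= 0.5
    if h_c >= 1.5:
        return "aliphatic"
    return "highly_unsaturated_phenolic"


def descriptors(ev: ElementVector) -> DescriptorSet:
    """All molecular descriptors of a composition."""
    c, h, n, o, s = ev.as_tuple()
    if c == 0:
        raise ValueError("descriptors undefined for carbon-free composition")
    h_c = h / c
    o_c = o / c
    ai = ai_mod_value(c, h, n, o, s)
    return DescriptorSet(
        h_c=h_c,
        o_c=o_c,
        dbe=dbe_value(c, h, n),
        ai_mod=ai,
        neutral_mass=exact_mass(ev),
        heteroatom_class=heteroatom_class(n, s),
        compound_class=classify_compound(ai, h_c),
    )


class _Lattice:
    """Vectorized candidate store for one (bounds, filters) configuration.

    Enumerates every (C, N, O, S) combination once; hydrogen counts are
    recovered per peak from the residual mass, so the per-peak cost is a
    handful of numpy passes rather than a 5-deep loop.
    """

    def __init__(self, cfg: AssignmentConfig):
        cfg.validate()
        self.cfg = cfg
        b = cfg.bounds
        c = np.arange(b["c"][0], b["c"][1] + 1)
        n = np.arange(b["n"][0], b["n"][1] + 1)
        o = np.arange(b["o"][0], b["o"][1] + 1)
        s = np.arange(b["s"][0], b["s"][1] + 1)
        C, N, O, S = np.meshgrid(c, n, o, s, indexing="ij")
        self.C = C.ravel()
        self.N = N.ravel()
        self.O = O.ravel()
        self.S = S.ravel()
        self.base_mass = (
            self.C * MASS_C + self.N * MASS_N + self.O * MASS_O + self.S * MASS_S
        )
        self.h_lo, self.h_hi = b["h"]

    def candidates(self, neutral_mass: float, tol_da: float) -> list[tuple[ElementVector, float]]:
        cfg = self.cfg
        residual = neutral_mass - self.base_mass
        h_float = residual / MASS_H
        out: list[tuple[ElementVector, float]] = []
        # H count must sit within tol of the residual; check the two
        # nearest integers (tol << 1 Da so at most one can match, but
        # floor/ceil keeps the search exact at the boundary).
        for h_cand in (np.floor(h_float), np.ceil(h_float)):
            h = h_cand.astype(np.int64)
            mass = self.base_mass + h * MASS_H
            err = neutral_mass - mass
            ok = (
                (np.abs(err) <= tol_da)
                & (h >= max(self.h_lo, 1))
                & (h <= self.h_hi)
            )
            if cfg.require_integer_nonneg_dbe:
                dbe2 = 2 + 2 * self.C - h + self.N  # 2*DBE, integer
                ok &= (dbe2 >= 0) & (dbe2 % 2 == 0)
            hc = h / self.C
            oc = self.O / self.C
            ok &= (hc >= cfg.hc_range[0]) & (hc <= cfg.hc_range[1])
            ok &= (oc >= cfg.oc_range[0]) & (oc <= cfg.oc_range[1])
            for i in np.flatnonzero(ok):
                ev = ElementVector(
                    int(self.C[i]), int(h[i]), int(self.N[i]),
                    int(self.O[i]), int(self.S[i]),
                )
                ppm = (exact_mass(ev) - neutral_mass) / neutral_mass * 1e6
                out.append((ev, ppm))
        # de-duplicate (floor == ceil at exact integers) and order by |error|
        seen: dict[ElementVector, float] = {}
        for ev, ppm in out:
            seen.setdefault(ev, ppm)
        return sorted(seen.items(), key=lambda t: (abs(t[1]), t[0].as_tuple()))


def assign_formulas(
    peaks: list[Peak], cfg: AssignmentConfig | None = None
) -> list[FormulaRecord]:
    """Assign CHNOS formulas to every peak in a calibrated peak list.

    For each peak, all compositions within ``cfg.bounds`` whose exact
    neutral mass matches ``mz_to_neutral(peak.mz)`` within
    ``cfg.tolerance_ppm`` and which pass the H/C, O/C and DBE filters are
    returned, ordered by |ppm error|; the first is the primary
    assignment. Peaks with no surviving candidate come back with an
    empty candidate list.
    """
    cfg = cfg or AssignmentConfig()
    lattice = _Lattice(cfg)
    records = []
    for peak in peaks:
        neutral = mz_to_neutral(peak.mz)
        tol_da = cfg.tolerance_ppm * 1e-6 * neutral
        records.append(FormulaRecord(peak=peak, candidates=lattice.candidates(neutral, tol_da)))
    return records
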