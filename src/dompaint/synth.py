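"""Synthetic dissolved-organic-matter and Cell Painting data generators.

Every pipeline stage in this package can be exercised without external
data: this module draws CHNOS formula libraries for four DOM source
archetypes, assembles a 33-sample study-scale intensity matrix, and
produces morphological well profiles and single-cell tables with a
planted sparse linear dependence of morphology on chemistry plus an
optional nuclear-shrinkage effect for "active" treatments.

The archetypes emulate the qualitative van Krevelen geometry of
standard humic reference materials:

* ``terrestrial_HA`` — aromatic/condensed, low H/C and O/C, N-rich;
* ``terrestrial_FA`` — highly oxygenated, tannin-like;
* ``microbial_FA``  — aliphatic, N/S-rich, masses below 600 Da
  (Pony-Lake-like fully microbial end member);
* ``aquatic``       — CHO-dominated, intermediate oxygenation.

All generators are bit-reproducible given (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chemo import IntensityMatrix
from .formula import AssignmentConfig, ElementVector, dbe_value, exact_mass
from .io import formula_string
from .morpho import WellProfileMatrix, WellSchema, default_schema

__all__ = [
    "ArchetypeSpec",
    "PlantedModel",
    "ARCHETYPES",
    "default_assignment",
    "generate_formula_library",
    "generate_study",
    "make_planted_model",
    "generate_cp_wells",
    "generate_single_cells",
]

#: Normal-distribution MAD/sd ratio, used to express planted shifts in
#: control-MAD units.
NORMAL_MAD = 0.6744897501960817


@dataclass(frozen=True)
class ArchetypeSpec:
    """Sampling ranges defining one DOM source archetype."""

    name: str
    c_range: tuple[int, int]
    hc_range: tuple[float, float]
    oc_range: tuple[float, float]
    p_n: float                      # probability a formula contains N
    p_s: float                      # probability a formula contains S
    mass_ceiling: float = 800.0
    intensity_sigma: float = 1.0    # log-normal spread of abundances

    def __post_init__(self) -> None:
        if not (0 <= self.p_n <= 1 and 0 <= self.p_s <= 1):
            raise ValueError("inclusion probabilities must be in [0, 1]")
        if self.c_range[0] < 1 or self.c_range[1] < self.c_range[0]:
            raise ValueError("invalid carbon range")


ARCHETYPES: dict[str, ArchetypeSpec] = {
    "terrestrial_HA": ArchetypeSpec(
        "terrestrial_HA", c_range=(12, 36), hc_range=(0.6, 1.1),
        oc_range=(0.2, 0.5), p_n=0.40, p_s=0.15,
    ),
    "terrestrial_FA": ArchetypeSpec(
        "terrestrial_FA", c_range=(10, 30), hc_range=(1.0, 1.6),
        oc_range=(0.5, 0.8), p_n=0.30, p_s=0.15,
    ),
    "microbial_FA": ArchetypeSpec(
        "microbial_FA", c_range=(8, 30), hc_range=(1.5, 2.0),
        oc_range=(0.1, 0.5), p_n=0.50, p_s=0.30, mass_ceiling=600.0,
    ),
    "aquatic": ArchetypeSpec(
        "aquatic", c_range=(10, 30), hc_range=(1.1, 1.7),
        oc_range=(0.4, 0.7), p_n=0.10, p_s=0.05,
    ),
}


def generate_formula_library(
    spec: ArchetypeSpec, n: int, seed: int,
    assignment_cfg: AssignmentConfig | None = None,
) -> list[ElementVector]:
    """Draw ``n`` distinct valid CHNOS formulas from an archetype.

    Every formula passes the assignment filters (H/C and O/C windows,
    non-negative integer DBE, mass ceiling); hydrogen parity is adjusted
    so DBE is an integer for the drawn nitrogen count.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    cfg = assignment_cfg or AssignmentConfig()
    rng = np.random.default_rng(seed)
    out: set[ElementVector] = set()
    max_draws = 2000 * n
    for _ in range(max_draws):
        c = int(rng.integers(spec.c_range[0], spec.c_range[1] + 1))
        h = int(round(c * rng.uniform(*spec.hc_range)))
        o = int(round(c * rng.uniform(*spec.oc_range)))
        nn = int(rng.integers(1, 3)) if rng.random() < spec.p_n else 0
        s = 1 if rng.random() < spec.p_s else 0
        if (h - nn) % 2 != 0:   # integer-DBE parity
            h += 1
        h = max(h, 1)
        if dbe_value(c, h, nn) < 0:
            continue
        hc, oc = h / c, o / c
        if not (cfg.hc_range[0] <= hc <= cfg.hc_range[1]):
            continue
        if not (cfg.oc_range[0] <= oc <= cfg.oc_range[1]):
            continue
        ev = ElementVector(c, h, nn, o, s)
        if exact_mass(ev) > spec.mass_ceiling:
            continue
        out.add(ev)
        if len(out) >= n:
            break
    else:
        raise RuntimeError(
            f"could not draw {n} distinct formulas for {spec.name} in {max_draws} tries"
        )
    return sorted(out)


_ARCHETYPE_META = {
    "terrestrial_HA": {"fraction": "HA", "sources": ["soil", "peat", "lignite"], "origin": "terrestrial"},
    "terrestrial_FA": {"fraction": "FA", "sources": ["soil", "peat", "lignite"], "origin": "terrestrial"},
    "microbial_FA": {"fraction": "FA", "sources": ["freshwater"], "origin": "aquatic"},
    "aquatic": {"fraction": "NOM", "sources": ["freshwater"], "origin": "aquatic"},
}


def default_assignment() -> dict[str, str]:
    """The default 33-sample design: sample id -> archetype.

    Nine terrestrial humic acids, eight terrestrial fulvic acids, two
    microbially derived fulvic acids and fourteen aquatic fractions.
    """
    design: dict[str, str] = {}
    for i in range(9):
        design[f"THA{i + 1:02d}"] = "terrestrial_HA"
    for i in range(8):
        design[f"TFA{i + 1:02d}"] = "terrestrial_FA"
    for i in range(2):
        design[f"MFA{i + 1:02d}"] = "microbial_FA"
    for i in range(14):
        design[f"AQ{i + 1:02d}"] = "aquatic"
    return design


def generate_study(
    assignment: dict[str, str] | None = None,
    n_formulas: int = 150,
    seed: int = 0,
    presence: float = 0.9,
    sample_sigma: float = 0.3,
) -> IntensityMatrix:
    """Generate a study-scale intensity matrix with metadata.

    Each archetype gets its own formula library with log-normal base
    abundances (spread ``intensity_sigma``); samples of that archetype
    share this abundance pattern, modulated by per-sample multiplicative
    log-normal noise (``sample_sigma``) and detection dropout that,
    as in real spectra, affects low-abundance formulas (overall rate
    ``1 - presence``, scaled down to zero for the base peak). Columns
    are the union of all libraries, absent formulas 0. The metadata
    carries fraction, source, origin and the ground-truth archetype.
    """
    if assignment is None:
        assignment = default_assignment()
    if not assignment:
        raise ValueError("empty sample assignment")
    rng = np.random.default_rng(seed)
    archetypes = sorted(set(assignment.values()))
    libraries = {
        a: generate_formula_library(
            ARCHETYPES[a], n_formulas, seed=int(rng.integers(2**31))
        )
        for a in archetypes
    }
    base_intensity = {
        a: rng.lognormal(0.0, ARCHETYPES[a].intensity_sigma, len(libraries[a]))
        for a in archetypes
    }
    columns = sorted(
        {formula_string(f) for lib in libraries.values() for f in lib}
    )
    col_idx = {c: i for i, c in enumerate(columns)}

    values = np.zeros((len(assignment), len(columns)))
    meta_rows = []
    for si, (sample, arch) in enumerate(sorted(assignment.items())):
        lib = libraries[arch]
        # dropout probability decreases with abundance rank: the base
        # peak is always detected, near-threshold peaks drop at ~2x the
        # average (1 - presence) rate
        ranks = np.argsort(np.argsort(base_intensity[arch])) / max(len(lib) - 1, 1)
        p_keep = 1.0 - 2.0 * (1.0 - presence) * (1.0 - ranks)
        present = rng.random(len(lib)) < p_keep
        if not present.any():
            present[0] = True
        inten = base_intensity[arch] * rng.lognormal(0.0, sample_sigma, len(lib))
        for f, p, w in zip(lib, present, inten):
            if p:
                values[si, col_idx[formula_string(f)]] = w
        m = _ARCHETYPE_META[arch]
        meta_rows.append(
            {
                "sample": sample,
                "fraction": m["fraction"],
                "source": m["sources"][si % len(m["sources"])],
                "origin": m["origin"],
                "archetype": arch,
            }
        )
    meta = pd.DataFrame(meta_rows).set_index("sample")
    vals = pd.DataFrame(values, index=meta.index, columns=columns)
    return IntensityMatrix(values=vals, meta=meta)


@dataclass
class PlantedModel:
    """Ground truth for the chemistry -> morphology dependence.

    ``scores`` are per-sample latent values; ``a`` (chemistry) and ``b``
    (morphology) are sparse loading vectors over the X columns and the
    well schema columns; wells are drawn as score * b + noise. Active
    treatments additionally receive a nuclear shrinkage of
    ``active_shift_mad`` control MADs.
    """

    scores: pd.Series
    a: pd.Series                # index = X feature names, sparse
    b: pd.Series                # index = well feature names, sparse
    noise_sd: float = 0.5
    active_shift_mad: float = 0.0
    active_samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if (self.a != 0).sum() == 0 or (self.b != 0).sum() == 0:
            raise ValueError("planted supports must be non-empty")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")

    @property
    def x_support(self) -> list[str]:
        return list(self.a.index[self.a != 0])

    @property
    def y_support(self) -> list[str]:
        return list(self.b.index[self.b != 0])


def make_planted_model(
    x_columns: list[str],
    samples: list[str],
    schema: WellSchema | None = None,
    k_x: int = 20,
    k_y: int = 10,
    noise_sd: float = 0.5,
    seed: int = 0,
    active_shift_mad: float = 0.0,
    active_samples: list[str] | None = None,
    x_values: pd.DataFrame | None = None,
) -> PlantedModel:
    """Draw a sparse latent model over given X columns and schema.

    When ``x_values`` (the chemical abundance matrix) is supplied, the
    latent score is the chemistry projection t = Z a (Z the TIC- and
    column-standardized matrix), standardized to unit variance — so
    morphology genuinely depends on the planted chemical support.
    Without it, scores are independent standard normals (useful for
    normalization tests that need no chemical coupling).
    """
    schema = schema or default_schema()
    rng = np.random.default_rng(seed)
    a = pd.Series(0.0, index=pd.Index(x_columns))
    sup_x = rng.choice(len(x_columns), size=k_x, replace=False)
    a.iloc[sup_x] = rng.choice([-1.0, 1.0], size=k_x)
    if x_values is not None:
        v = x_values.loc[samples, x_columns].astype(float)
        v = v.div(v.sum(axis=1), axis=0)        # TIC
        sd = v.std(axis=0, ddof=1)
        z = (v - v.mean(axis=0)).div(sd.where(sd > 0, 1.0), axis=1)
        t = z.to_numpy() @ a.to_numpy()
        if t.std(ddof=1) == 0:
            raise ValueError("planted chemistry support has no variance")
        scores = pd.Series((t - t.mean()) / t.std(ddof=1), index=samples)
    else:
        scores = pd.Series(rng.standard_normal(len(samples)), index=samples)
    y_cols = schema.columns
    b = pd.Series(0.0, index=pd.Index(y_cols))
    sup_y = rng.choice(len(y_cols), size=k_y, replace=False)
    b.iloc[sup_y] = rng.choice([-1.0, 1.0], size=k_y)
    return PlantedModel(
        scores=scores, a=a, b=b, noise_sd=noise_sd,
        active_shift_mad=active_shift_mad,
        active_samples=list(active_samples or []),
    )


def generate_cp_wells(
    planted: PlantedModel,
    replicates: int = 6,
    n_controls: int = 24,
    seed: int = 0,
    schema: WellSchema | None = None,
    plate: str = "P1",
) -> tuple[WellProfileMatrix, pd.DataFrame]:
    """Draw raw well-level profiles from the planted model.

    Each sample gets ``replicates`` wells at score * b plus Gaussian
    noise; control wells are baseline noise. Active samples additionally
    have every nucleus-compartment mean feature shifted by
    ``active_shift_mad`` control MADs. Returns the raw matrix and a
    per-sample truth table (latent score, is_active).
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    schema = schema or default_schema()
    rng = np.random.default_rng(seed)
    cols = schema.columns
    b = planted.b.reindex(cols).fillna(0.0).to_numpy()
    # MAD of the control well distribution (normal noise)
    control_mad = NORMAL_MAD * planted.noise_sd
    nucleus_means = [
        i for i, c in enumerate(cols)
        if c.startswith("nucleus_") and c.endswith("__mean")
    ]

    rows, labels = [], []
    well_no = 1
    for sample in planted.scores.index:
        effect = planted.scores[sample] * b
        if sample in planted.active_samples and planted.active_shift_mad != 0:
            effect = effect.copy()
            effect[nucleus_means] += planted.active_shift_mad * control_mad
        for _ in range(replicates):
            rows.append(effect + rng.normal(0, planted.noise_sd, len(cols)))
            labels.append({"plate": plate, "well": f"W{well_no:03d}",
                           "treatment": sample, "is_control": False})
            well_no += 1
    for _ in range(n_controls):
        rows.append(rng.normal(0, planted.noise_sd, len(cols)))
        labels.append({"plate": plate, "well": f"W{well_no:03d}",
                       "treatment": "DMSO", "is_control": True})
        well_no += 1

    wells = WellProfileMatrix(
        values=pd.DataFrame(rows, columns=cols),
        labels=pd.DataFrame(labels),
        state="raw",
    )
    truth = pd.DataFrame(
        {
            "score": planted.scores,
            "is_active": [s in planted.active_samples for s in planted.scores.index],
        }
    )
    return wells, truth


SINGLE_CELL_FEATURES = ["nuclear_area", "nuclear_diameter", "cell_area"]


def generate_single_cells(
    treatments: list[str],
    active: list[str],
    n_cells: int = 60,
    replicates: int = 6,
    n_control_wells: int = 12,
    active_shift_mad: float = -5.0,
    seed: int = 0,
    plate: str = "P1",
) -> pd.DataFrame:
    """Draw a single-cell table with a planted nuclear-shrinkage effect.

    Cells carry nuclear area (px^2), its derived diameter, and cell
    area. Active treatments have the nuclear area of every cell shifted
    by ``active_shift_mad`` control MADs of the well-mean distribution
    (well-to-well plus cell-sampling variability); diameter and cell
    area co-shrink through their geometric and biological coupling.
    """
    if n_cells < 2:
        raise ValueError("n_cells must be >= 2")
    rng = np.random.default_rng(seed)
    area_mu, area_sd_cell, area_sd_well = 180.0, 30.0, 6.0
    cell_mu, cell_sd_cell = 1600.0, 250.0
    # sd of a control well's mean nuclear area
    well_mean_sd = np.hypot(area_sd_well, area_sd_cell / np.sqrt(n_cells))
    shift = active_shift_mad * NORMAL_MAD * well_mean_sd

    rows = []
    well_no = 1

    def emit(treatment: str, is_control: bool, area_shift: float) -> None:
        nonlocal well_no
        well_eff = rng.normal(0, area_sd_well)
        areas = np.maximum(
            rng.normal(area_mu + area_shift + well_eff, area_sd_cell, n_cells), 5.0
        )
        diam = 2 * np.sqrt(areas / np.pi) + rng.normal(0, 0.2, n_cells)
        # cell area scales with nuclear area (shrinkage co-occurs)
        cell_area = np.maximum(
            cell_mu + 4.0 * (areas - area_mu) + rng.normal(0, cell_sd_cell, n_cells),
            20.0,
        )
        for a, d, ca in zip(areas, diam, cell_area):
            rows.append(
                {
                    "plate": plate, "well": f"W{well_no:03d}",
                    "treatment": treatment, "is_control": is_control,
                    "nuclear_area": a, "nuclear_diameter": d, "cell_area": ca,
                }
            )
        well_no += 1

    for t in treatments:
        for _ in range(replicates):
            emit(t, False, shift if t in active else 0.0)
    for _ in range(n_control_wells):
        emit("DMSO", True, 0.0)
    return pd.DataFrame(rows)
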