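"""Well-level morphological profiling and activity scoring.

Single-cell measurements from a high-content Cell Painting assay are
aggregated into well-level profiles (per-feature means and unbiased
variances plus across-cell Pearson correlations for a configurable list
of feature pairs), robust-z-scored per plate against the vehicle-control
wells (rMAD: subtract the control median, divide by the control MAD),
condensed into per-treatment median profiles, and scored for overall
morphological activity as the Global Euclidean Distance (GED) from the
control origin. A simple fluorescence-interference assessment implements
the blank-subtraction arithmetic for sample autofluorescence and
dye-quenching readouts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "WellSchema",
    "WellProfileMatrix",
    "aggregate_wells",
    "rmad_normalize",
    "median_profiles",
    "global_euclidean_distance",
    "activity_partition",
    "interference_assessment",
    "default_schema",
]

LABEL_COLUMNS = ("plate", "well", "treatment", "is_control")

_COMPARTMENTS = ("nucleus", "cell", "cytoplasm", "mito", "er", "rna", "golgi", "membrane")
_MEASURES = (
    "area", "diameter", "perimeter", "shape_p2a", "shape_lwr",
    "intensity_mean", "intensity_total", "intensity_std",
    "texture_contrast", "texture_entropy", "spot_count", "radial_mean",
    "edge_intensity",
)


@dataclass
class WellSchema:
    """Defines the well-level feature layout.

    ``base_features`` each yield a mean and a variance column;
    ``correlation_pairs`` each yield one across-cell Pearson correlation
    column. The default schema (100 base features, 72 pairs) gives the
    standard 272-column profile.
    """

    base_features: list[str]
    correlation_pairs: list[tuple[str, str]]

    @property
    def n_features(self) -> int:
        return 2 * len(self.base_features) + len(self.correlation_pairs)

    @property
    def columns(self) -> list[str]:
        return (
            [f"{f}__mean" for f in self.base_features]
            + [f"{f}__var" for f in self.base_features]
            + [f"corr__{a}__{b}" for a, b in self.correlation_pairs]
        )


def default_schema() -> WellSchema:
    """100 base features (means + variances) and 72 correlation pairs: 272 columns."""
    base = [f"{c}_{m}" for c in _COMPARTMENTS for m in _MEASURES][:100]
    pairs = []
    # deterministic ring of pairs over the first base features
    for i in range(72):
        a = base[i % len(base)]
        b = base[(i * 7 + 11) % len(base)]
        if a == b:
            b = base[(i * 7 + 12) % len(base)]
        pairs.append((a, b))
    return WellSchema(base_features=base, correlation_pairs=pairs)


@dataclass
class WellProfileMatrix:
    """Wells x morphological features with treatment/control labels.

    ``labels`` carries plate, well, treatment, is_control per row of
    ``values``; ``state`` is 'raw' or 'rmad_normalized'.
    """

    values: pd.DataFrame
    labels: pd.DataFrame
    state: str = "raw"
    dropped_features: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = set(LABEL_COLUMNS) - set(self.labels.columns)
        if missing:
            raise ValueError(f"labels missing columns {sorted(missing)}")
        if not self.values.index.equals(self.labels.index):
            raise ValueError("values and labels must share an index")


def aggregate_wells(cells: pd.DataFrame, schema: WellSchema) -> WellProfileMatrix:
    """Collapse a single-cell table into well-level profiles.

    Per well: mean and unbiased (n-1) variance of each base feature
    across cells, and across-cell Pearson correlation for each schema
    pair. Wells with a single cell get variance 0 and NaN correlations
    (flagged missing).
    """
    missing = set(LABEL_COLUMNS) - set(cells.columns)
    if missing:
        raise ValueError(f"single-cell table missing columns {sorted(missing)}")
    for f in schema.base_features:
        if f not in cells.columns:
            raise ValueError(f"single-cell table missing feature {f!r}")
    if not np.isfinite(cells[schema.base_features].to_numpy()).all():
        raise ValueError("non-finite measurement values")

    rows, labels = [], []
    for (plate, well), grp in cells.groupby(["plate", "well"], sort=True):
        x = grp[schema.base_features].to_numpy(dtype=float)
        n = len(x)
        means = x.mean(axis=0)
        if n >= 2:
            variances = x.var(axis=0, ddof=1)
        else:
            variances = np.zeros(x.shape[1])
        corrs = []
        col = {f: i for i, f in enumerate(schema.base_features)}
        for a, b in schema.correlation_pairs:
            if n < 2:
                corrs.append(np.nan)
                continue
            xa, xb = x[:, col[a]], x[:, col[b]]
            sa, sb = xa.std(), xb.std()
            if sa == 0 or sb == 0:
                corrs.append(np.nan)
            else:
                corrs.append(float(np.corrcoef(xa, xb)[0, 1]))
        rows.append(np.concatenate([means, variances, corrs]))
        labels.append(
            {
                "plate": plate,
                "well": well,
                "treatment": grp["treatment"].iloc[0],
                "is_control": bool(grp["is_control"].iloc[0]),
            }
        )
    values = pd.DataFrame(rows, columns=schema.columns)
    return WellProfileMatrix(values=values, labels=pd.DataFrame(labels), state="raw")


def _mad(x: np.ndarray, scale: float = 1.0) -> np.ndarray:
    return np.median(np.abs(x - np.median(x, axis=0)), axis=0) * scale


def rmad_normalize(
    wells: WellProfileMatrix, consistency_constant: bool = False
) -> WellProfileMatrix:
    """Robust-z-score each feature per plate against that plate's controls.

    z = (x - median(controls)) / MAD(controls). The raw MAD is used by
    default; set ``consistency_constant`` to scale by 1.4826. Features
    whose control MAD is 0 on any plate are dropped (and logged), as are
    features with missing values.
    """
    if wells.state != "raw":
        raise ValueError("input wells are already normalized")
    vals = wells.values.copy()
    dropped: set[str] = set(vals.columns[vals.isna().any(axis=0)])
    scale = 1.4826 if consistency_constant else 1.0
    out = pd.DataFrame(index=vals.index, columns=vals.columns, dtype=float)
    for plate, idx in wells.labels.groupby("plate").groups.items():
        ctrl_idx = [i for i in idx if wells.labels.loc[i, "is_control"]]
        if not ctrl_idx:
            raise ValueError(f"plate {plate!r} has no control wells")
        ctrl = vals.loc[ctrl_idx].to_numpy(dtype=float)
        med = np.median(ctrl, axis=0)
        mad = _mad(ctrl, scale)
        zero = mad == 0
        dropped.update(vals.columns[zero])
        with np.errstate(divide="ignore", invalid="ignore"):
            out.loc[idx] = (vals.loc[idx].to_numpy(dtype=float) - med) / mad
    keep = [c for c in vals.columns if c not in dropped]
    if dropped:
        logger.info("rmad_normalize dropped %d feature(s): zero control MAD or missing", len(dropped))
    return WellProfileMatrix(
        values=out[keep],
        labels=wells.labels,
        state="rmad_normalized",
        dropped_features=sorted(dropped),
    )


def median_profiles(wells: WellProfileMatrix) -> pd.DataFrame:
    """Component-wise median over the replicate wells of each treatment."""
    grouped = wells.values.groupby(wells.labels["treatment"].to_numpy()).median()
    grouped.index.name = "treatment"
    return grouped


def global_euclidean_distance(profile: pd.Series | np.ndarray) -> float:
    """Euclidean norm of an rMAD-normalized median profile.

    With controls centered at the origin this measures the overall
    morphological deviation from the vehicle condition.
    """
    x = np.asarray(profile, dtype=float)
    if x.size == 0:
        raise ValueError("empty feature set")
    return float(np.linalg.norm(x))


def activity_partition(scores: pd.Series) -> pd.Series:
    """Split GED scores into 'high' / 'low' activity groups.

    Exhaustive search over the sorted split points for the two-group
    partition maximizing the between-group variance (Otsu's criterion in
    one dimension); the upper group is labeled 'high'. If all scores are
    identical, everything is 'low' and a warning is emitted.
    """
    if len(scores) < 2:
        raise ValueError("activity partition requires at least 2 samples")
    x = scores.to_numpy(dtype=float)
    order = np.argsort(x, kind="stable")
    xs = x[order]
    if xs[0] == xs[-1]:
        warnings.warn("all activity scores identical; labelling all samples low")
        return pd.Series("low", index=scores.index, name="activity")
    n = len(xs)
    best_cut, best_between = 1, -np.inf
    for cut in range(1, n):
        lo, hi = xs[:cut], xs[cut:]
        between = cut * (lo.mean() - xs.mean()) ** 2 + (n - cut) * (hi.mean() - xs.mean()) ** 2
        if between > best_between:
            best_between, best_cut = between, cut
    threshold = xs[best_cut]  # first member of the upper group
    labels = np.where(x >= threshold, "high", "low")
    return pd.Series(labels, index=scores.index, name="activity")


def interference_assessment(readouts: pd.DataFrame) -> pd.DataFrame:
    """Autofluorescence and dye-quenching deltas from a no-cell experiment.

    ``readouts`` columns: sample, dye, channel, concentration_ppm,
    readout. Rows with dye == 'none' are sample-alone measurements
    (sample == 'PBS' is the buffer blank); rows with sample == 'none'
    are dye-alone. Per (sample, dye, channel, concentration):
    autofluorescence = sample_alone - blank; dye_effect = mixture -
    dye_alone (negative values indicate quenching).
    """
    req = {"sample", "dye", "channel", "concentration_ppm", "readout"}
    missing = req - set(readouts.columns)
    if missing:
        raise ValueError(f"readout table missing columns {sorted(missing)}")

    blanks = readouts[(readouts["sample"] == "PBS") & (readouts["dye"] == "none")]
    blank_by_channel = blanks.set_index("channel")["readout"]
    dye_alone = readouts[(readouts["sample"] == "none") & (readouts["dye"] != "none")]
    dye_key = dye_alone.set_index(["dye", "channel", "concentration_ppm"])["readout"]

    rows = []
    for _, r in readouts.iterrows():
        if r["sample"] in ("PBS", "none"):
            continue
        if r["dye"] == "none":  # sample alone
            if r["channel"] not in blank_by_channel.index:
                raise ValueError(f"missing PBS blank for channel {r['channel']!r}")
            rows.append(
                {
                    "sample": r["sample"],
                    "dye": "none",
                    "channel": r["channel"],
                    "concentration_ppm": r["concentration_ppm"],
                    "kind": "autofluorescence",
                    "delta": r["readout"] - blank_by_channel[r["channel"]],
                }
            )
        else:  # sample + dye mixture
            key = (r["dye"], r["channel"], r["concentration_ppm"])
            if key not in dye_key.index:
                raise ValueError(f"missing dye-alone readout for {key}")
            delta = r["readout"] - dye_key[key]
            rows.append(
                {
                    "sample": r["sample"],
                    "dye": r["dye"],
                    "channel": r["channel"],
                    "concentration_ppm": r["concentration_ppm"],
                    "kind": "quenching" if delta < 0 else "dye_effect",
                    "delta": delta,
                }
            )
    return pd.DataFrame(rows)
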