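"""Tumor-enriched regions, density and nearest-neighbor interaction features.

The tumor-enriched region of a sample is the level set of a kernel density
map: unit impulses at the (pixel-rounded) centroids of tumor cells,
convolved with a unit-mass 2-D Gaussian of sigma = 15 px, thresholded at
0.0005 cells/px^2.  With these constants a single isolated tumor cell peaks
at ``1/(2 pi sigma^2) ~ 7.07e-4`` and already clears the threshold with a
~12.5 px disk.  The complement is the tumor-unenriched region.

Per-sample features:

* density of subtype s = (# s-cells with centroid in the region) / (total
  tumor cells in the sample) — note non-tumor densities may exceed 1;
* interaction Avg.C_m^j = N_mj / N_m, where N_m counts in-region m-cells and
  N_mj counts neighbor pairs whose m-role endpoint is in-region and whose
  partner has subtype j; two cells are neighbors when their centroids are
  strictly closer than 20 um.  Avg.C is missing (NaN) when N_m = 0.

Features are compared between survivor classes by unpaired two-sample
t tests (pooled variance) with Benjamini-Hochberg correction across all
tested features.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
import scipy.spatial
import scipy.stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TumorRegionMask",
    "tumor_enriched_region",
    "density_features",
    "neighbor_pairs",
    "interaction_features",
    "group_compare",
    "sample_feature_matrix",
]

DEFAULT_SIGMA_PX = 15.0
DEFAULT_THRESHOLD = 0.0005
DEFAULT_NEIGHBOR_RADIUS_UM = 20.0


@dataclass
class TumorRegionMask:
    mask: np.ndarray  # boolean, True = tumor-enriched
    sigma_px: float
    threshold: float
    empty: bool = False  # True when the sample had no tumor cells

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())


def tumor_enriched_region(
    tumor_centroids_px: np.ndarray,
    image_shape: tuple[int, int],
    sigma_px: float = DEFAULT_SIGMA_PX,
    threshold: float = DEFAULT_THRESHOLD,
) -> TumorRegionMask:
    """Threshold the Gaussian-smoothed tumor-centroid density map.

    ``tumor_centroids_px`` is an (n, 2) array of (y, x) pixel coordinates.
    Centroids are rounded to the nearest pixel, counted into an impulse
    image, convolved with a normalized Gaussian (truncated at 4 sigma), and
    the mask is ``density >= threshold``.  No tumor cells yields an
    all-False mask flagged ``empty``.
    """
    h, w = image_shape
    centroids = np.asarray(tumor_centroids_px, dtype=float).reshape(-1, 2)
    if centroids.shape[0] == 0:
        return TumorRegionMask(
            mask=np.zeros(image_shape, dtype=bool),
            sigma_px=sigma_px, threshold=threshold, empty=True,
        )
    ys = np.clip(np.rint(centroids[:, 0]).astype(int), 0, h - 1)
    xs = np.clip(np.rint(centroids[:, 1]).astype(int), 0, w - 1)
    impulses = np.zeros(image_shape, dtype=float)
    np.add.at(impulses, (ys, xs), 1.0)
    density = ndi.gaussian_filter(impulses, sigma=sigma_px, mode="constant", truncate=4.0)
    return TumorRegionMask(mask=density >= threshold, sigma_px=sigma_px, threshold=threshold)


def _in_region(table: pd.DataFrame, region: TumorRegionMask, pixel_size_um: float) -> np.ndarray:
    h, w = region.mask.shape
    ys = np.clip(np.rint(table["y_um"].to_numpy() / pixel_size_um).astype(int), 0, h - 1)
    xs = np.clip(np.rint(table["x_um"].to_numpy() / pixel_size_um).astype(int), 0, w - 1)
    return region.mask[ys, xs]


def density_features(
    table: pd.DataFrame,
    region: TumorRegionMask,
    tumor_subtypes: Sequence[str],
    subtypes: Sequence[str] | None = None,
    pixel_size_um: float = 1.0,
) -> pd.Series:
    """Per-subtype in-region cell count divided by total tumor cells.

    ``table`` is one sample's cell table (columns ``x_um, y_um, subtype``).
    Raises if the sample has no tumor cells (features undefined).
    """
    n_tumor = int(table["subtype"].isin(tumor_subtypes).sum())
    if n_tumor == 0:
        raise ValueError("sample has no tumor cells; density features undefined")
    inside = _in_region(table, region, pixel_size_um)
    if subtypes is None:
        subtypes = sorted(table["subtype"].unique())
    counts = table.loc[inside, "subtype"].value_counts()
    return pd.Series(
        {s: counts.get(s, 0) / n_tumor for s in subtypes}, name="density", dtype=float
    )


def neighbor_pairs(table: pd.DataFrame, radius_um: float = DEFAULT_NEIGHBOR_RADIUS_UM) -> np.ndarray:
    """All unordered cell index pairs with centroid distance strictly < radius.

    Returns an (n_pairs, 2) array of positional indices into ``table``.
    Uses a k-d tree but reproduces the exact all-pairs result (boundary
    pairs at exactly the radius are excluded).
    """
    pts = table[["x_um", "y_um"]].to_numpy(dtype=float)
    if len(pts) < 2:
        return np.empty((0, 2), dtype=int)
    tree = scipy.spatial.cKDTree(pts)
    pairs = tree.query_pairs(r=radius_um, output_type="ndarray")
    if pairs.size == 0:
        return pairs.reshape(0, 2)
    d = np.linalg.norm(pts[pairs[:, 0]] - pts[pairs[:, 1]], axis=1)
    return pairs[d < radius_um]


def interaction_features(
    table: pd.DataFrame,
    pairs: np.ndarray,
    region: TumorRegionMask,
    subtypes: Sequence[str] | None = None,
    pixel_size_um: float = 1.0,
    require_partner_in_region: bool = False,
) -> pd.Series:
    """Avg.C_m^j for every ordered subtype pair (m, j) of one sample.

    N_m restricts the m-role endpoint to the tumor-enriched region; the
    partner is unrestricted by default (``require_partner_in_region``
    switches on the stricter convention).  Index is ``"AvgC_<m>__<j>"``;
    NaN where N_m = 0.
    """
    if subtypes is None:
        subtypes = sorted(table["subtype"].unique())
    sub = table["subtype"].to_numpy()
    inside = _in_region(table, region, pixel_size_um)
    n_in = {m: int(((sub == m) & inside).sum()) for m in subtypes}

    pair_counts: dict[tuple[str, str], int] = {(m, j): 0 for m in subtypes for j in subtypes}
    for a, b in pairs:
        for m_idx, j_idx in ((a, b), (b, a)):  # both ordered roles
            if not inside[m_idx]:
                continue
            if require_partner_in_region and not inside[j_idx]:
                continue
            key = (sub[m_idx], sub[j_idx])
            if key in pair_counts:
                pair_counts[key] += 1
    values = {}
    for m in subtypes:
        for j in subtypes:
            nm = n_in[m]
            values[f"AvgC_{m}__{j}"] = pair_counts[(m, j)] / nm if nm > 0 else np.nan
    return pd.Series(values, name="AvgC", dtype=float)


def sample_feature_matrix(
    cell_table: pd.DataFrame,
    tumor_subtypes: Sequence[str],
    image_shape: tuple[int, int],
    pixel_size_um: float = 1.0,
    sigma_px: float = DEFAULT_SIGMA_PX,
    threshold: float = DEFAULT_THRESHOLD,
    radius_um: float = DEFAULT_NEIGHBOR_RADIUS_UM,
    kind: str = "both",
) -> pd.DataFrame:
    """Convenience driver: per-sample density and/or Avg.C feature rows.

    ``cell_table`` holds all samples (columns ``sample_id, x_um, y_um,
    subtype``).  Returns a samples x features DataFrame; kind is
    ``"density"``, ``"interaction"`` or ``"both"``.
    """
    subtypes = sorted(cell_table["subtype"].unique())
    rows = {}
    for sample_id, sub in cell_table.groupby("sample_id"):
        sub = sub.reset_index(drop=True)
        centroids = np.column_stack(
            [sub["y_um"].to_numpy() / pixel_size_um, sub["x_um"].to_numpy() / pixel_size_um]
        )
        tumor_mask = sub["subtype"].isin(tumor_subtypes).to_numpy()
        region = tumor_enriched_region(
            centroids[tumor_mask], image_shape, sigma_px=sigma_px, threshold=threshold
        )
        parts = []
        if kind in ("density", "both"):
            dens = density_features(
                sub, region, tumor_subtypes, subtypes=subtypes, pixel_size_um=pixel_size_um
            )
            parts.append(dens.rename(lambda s: f"density_{s}"))
        if kind in ("interaction", "both"):
            pairs = neighbor_pairs(sub, radius_um=radius_um)
            parts.append(
                interaction_features(
                    sub, pairs, region, subtypes=subtypes, pixel_size_um=pixel_size_um
                )
            )
        rows[sample_id] = pd.concat(parts)
    return pd.DataFrame(rows).T.rename_axis("sample_id")


def group_compare(
    features: pd.DataFrame,
    class_labels: pd.Series,
    positive_class: str = "LTS",
    alpha: float = 0.05,
    max_missing_frac: float = 0.5,
) -> pd.DataFrame:
    """Unpaired t tests (pooled variance) per feature with BH correction.

    ``features`` is samples x features; ``class_labels`` maps sample to
    class.  Features missing in more than ``max_missing_frac`` of samples
    are excluded (column ``excluded``); remaining missing values are
    dropped pairwise.  Returns one row per feature with means, t, raw and
    BH-adjusted p, and the direction of change in the positive class.
    """
    labels = class_labels.reindex(features.index)
    classes = labels.unique()
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {list(classes)}")
    other = [c for c in classes if c != positive_class][0]
    records = []
    for feat in features.columns:
        x = features[feat]
        missing_frac = x.isna().mean()
        a = x[labels == positive_class].dropna()
        b = x[labels == other].dropna()
        rec = {
            "feature": feat,
            f"mean_{positive_class}": a.mean(),
            f"mean_{other}": b.mean(),
            "excluded": missing_frac > max_missing_frac or len(a) < 2 or len(b) < 2,
        }
        if not rec["excluded"]:
            t, p = scipy.stats.ttest_ind(a, b, equal_var=True)
            rec["t"] = float(t)
            rec["p_raw"] = float(p)
            rec["direction"] = "increased" if a.mean() > b.mean() else "decreased"
        records.append(rec)
    out = pd.DataFrame.from_records(records).set_index("feature")
    tested = out.index[~out["excluded"] & out["p_raw"].notna()]
    out["p_adj"] = np.nan
    if len(tested):
        _, p_adj, _, _ = multipletests(out.loc[tested, "p_raw"], method="fdr_bh")
        out.loc[tested, "p_adj"] = p_adj
    out["significant"] = out["p_adj"] < alpha
    return out
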