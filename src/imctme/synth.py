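"""Synthetic tissue images, survivor cohorts, and expression matrices.

Every downstream stage of the pipeline (segmentation, phenotyping, spatial
features, survival modelling, omics correlation) is exercised against data
from this module, because the generators carry full ground truth: each cell
has a known subtype, each cohort a registry of planted class effects, each
expression matrix a list of genes with known correlation targets.

The generative model is deliberately simple but shaped like the real thing:

* cells are axis-aligned ellipses with jittered radii; tumor subtypes are
  drawn toward a few cluster centers (tumor nests), non-tumor subtypes are
  dispersed uniformly; overlaps are resolved by letting the later label win,
  so the segmentation stage sees touching cells;
* per-channel pixel intensities are Poisson draws around a per-cell mean
  taken from the subtype's marker profile (ion-counting statistics), with a
  gamma jitter whose coefficient of variation is the profile's dispersion;
* one global integer seed feeds a hierarchical ``SeedSequence`` scheme: each
  sample derives a child seed, so enlarging a cohort never perturbs the
  samples already generated.

Planted class effects come in two kinds.  A *density* effect shifts one
subtype's abundance between long-term (LTS) and short-term (STS) survivor
samples.  An *interaction* effect relocates a fraction of one subtype's
cells to within a few microns of another subtype's cells in LTS samples,
raising the nearest-neighbor interaction statistic without changing counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .stacks import ImageStack, LabelMask

__all__ = [
    "TissueSpec",
    "CohortSpec",
    "GroundTruth",
    "CohortSample",
    "generate_tissue",
    "apply_spillover",
    "generate_cohort",
    "generate_expression",
    "default_tissue_spec",
    "default_cohort_spec",
    "cohort_cell_table",
    "cohort_survival_table",
]

NUCLEAR_MARKERS = ("H3", "DNA191", "DNA193")


@dataclass
class TissueSpec:
    """Parameters of one synthetic tissue image.

    ``subtype_profiles`` maps subtype -> marker -> (mean, dispersion) where
    the mean is the expected ion count per pixel and the dispersion is the
    coefficient of variation of the per-cell gamma jitter.
    """

    image_shape: tuple[int, int] = (300, 300)
    subtype_profiles: Mapping[str, Mapping[str, tuple[float, float]]] = field(default_factory=dict)
    subtype_weights: Mapping[str, float] = field(default_factory=dict)
    tumor_subtypes: tuple[str, ...] = ()
    n_cluster_centers: int = 3
    cluster_spread_px: float = 30.0
    cell_radius_range: tuple[float, float] = (3.0, 5.0)
    n_cells: int = 250
    background_rate: float = 0.05
    min_spacing_px: float = 0.0  # soft minimum centroid distance (0 = off)
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.image_shape
        if h <= 0 or w <= 0:
            raise ValueError("image_shape must be positive")
        if self.cell_radius_range[0] < 1:
            raise ValueError("minimum cell radius must be >= 1 pixel")
        if self.cell_radius_range[0] > self.cell_radius_range[1]:
            raise ValueError("cell_radius_range must be (min, max)")
        unknown = set(self.tumor_subtypes) - set(self.subtype_profiles)
        if unknown:
            raise ValueError(f"tumor subtypes {sorted(unknown)} not in subtype_profiles")
        if self.subtype_weights and set(self.subtype_weights) != set(self.subtype_profiles):
            raise ValueError("subtype_weights keys must match subtype_profiles keys")

    @property
    def subtypes(self) -> list[str]:
        return list(self.subtype_profiles)

    @property
    def markers(self) -> list[str]:
        first = next(iter(self.subtype_profiles.values()), {})
        return list(first)

    def weights(self) -> dict[str, float]:
        if self.subtype_weights:
            w = dict(self.subtype_weights)
        else:
            w = {s: 1.0 for s in self.subtypes}
        total = sum(w.values())
        return {s: v / total for s, v in w.items()}


@dataclass
class CohortSpec:
    """Parameters of a two-class (LTS/STS) synthetic cohort."""

    n_samples_per_class: Mapping[str, int] = field(
        default_factory=lambda: {"LTS": 21, "STS": 20}
    )
    planted_density_effects: Mapping[str, float] = field(default_factory=dict)
    planted_interaction_effects: Mapping[tuple[str, str], float] = field(default_factory=dict)
    age_distribution: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"LTS": (58.0, 9.0), "STS": (63.0, 9.0)}
    )
    survival_months: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"LTS": (60.0, 140.0), "STS": (4.0, 20.0)}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for cls in ("LTS", "STS"):
            if cls not in self.n_samples_per_class:
                raise ValueError(f"n_samples_per_class missing class {cls!r}")
        lo, _ = self.survival_months["LTS"]
        if lo < 60:
            raise ValueError("LTS survival months must be >= 60")
        _, hi = self.survival_months["STS"]
        if hi > 20:
            raise ValueError("STS survival months must be <= 20")
        for eff in self.planted_density_effects.values():
            if not math.isfinite(eff):
                raise ValueError("planted density effects must be finite")
        for eff in self.planted_interaction_effects.values():
            if not (0.0 <= eff <= 1.0):
                raise ValueError("planted interaction strengths must lie in [0, 1]")


@dataclass
class GroundTruth:
    """True cell layout of one generated sample plus the effect registry."""

    cells: pd.DataFrame  # cell_id, subtype, x_px, y_px, rx, ry
    class_label: str | None = None
    registry: list[tuple] = field(default_factory=list)

    @property
    def n_cells(self) -> int:
        return len(self.cells)


@dataclass
class CohortSample:
    sample_id: str
    stack: ImageStack | None
    mask: LabelMask | None
    truth: GroundTruth
    survival: dict


def _place_cells(
    spec: TissueSpec, rng: np.random.Generator
) -> tuple[pd.DataFrame, np.ndarray]:
    h, w = spec.image_shape
    rmin, rmax = spec.cell_radius_range
    # Overlap is allowed, but refuse layouts that could not fit even at
    # perfect packing: they signal a mis-specified experiment.
    needed = spec.n_cells * math.pi * rmin * rmin
    if needed > 0.85 * h * w:
        achievable = int(0.85 * h * w / (math.pi * rmin * rmin))
        raise ValueError(
            f"cannot place {spec.n_cells} cells of radius >= {rmin} px in a "
            f"{h}x{w} image; at most ~{achievable} cells are achievable"
        )
    weights = spec.weights()
    subtypes = rng.choice(spec.subtypes, size=spec.n_cells, p=[weights[s] for s in spec.subtypes])

    margin = rmax + 1
    centers = np.column_stack(
        [
            rng.uniform(margin, h - margin, size=spec.n_cluster_centers),
            rng.uniform(margin, w - margin, size=spec.n_cluster_centers),
        ]
    )
    ys = np.empty(spec.n_cells)
    xs = np.empty(spec.n_cells)
    is_tumor = np.isin(subtypes, list(spec.tumor_subtypes))
    for i in range(spec.n_cells):
        # soft spacing: retry a bounded number of times, then accept anyway
        for _attempt in range(50):
            if is_tumor[i] and spec.n_cluster_centers > 0:
                cy, cx = centers[rng.integers(spec.n_cluster_centers)]
                y = cy + rng.normal(0, spec.cluster_spread_px)
                x = cx + rng.normal(0, spec.cluster_spread_px)
            else:
                y = rng.uniform(margin, h - margin)
                x = rng.uniform(margin, w - margin)
            y = float(np.clip(y, margin, h - margin - 1))
            x = float(np.clip(x, margin, w - margin - 1))
            if spec.min_spacing_px <= 0 or i == 0:
                break
            d2 = (ys[:i] - y) ** 2 + (xs[:i] - x) ** 2
            if d2.min() >= spec.min_spacing_px**2:
                break
        ys[i] = y
        xs[i] = x
    radii = rng.uniform(rmin, rmax, size=(spec.n_cells, 2))
    cells = pd.DataFrame(
        {
            "cell_id": np.arange(1, spec.n_cells + 1),
            "subtype": subtypes,
            "x_px": xs,
            "y_px": ys,
            "rx": radii[:, 0],
            "ry": radii[:, 1],
        }
    )
    return cells, centers


def _rasterize(cells: pd.DataFrame, shape: tuple[int, int]) -> np.ndarray:
    """Paint ellipse cells into a label image; later labels overwrite.

    Every cell is guaranteed at least one pixel: a cell fully covered by
    later neighbors reclaims a pixel near its centroid from an owner that
    can spare one, so mask labels and ground-truth cells stay in 1:1
    correspondence.
    """
    labels = np.zeros(shape, dtype=np.int32)
    h, w = shape
    for row in cells.itertuples(index=False):
        y0 = max(int(row.y_px - row.ry), 0)
        y1 = min(int(row.y_px + row.ry) + 1, h)
        x0 = max(int(row.x_px - row.rx), 0)
        x1 = min(int(row.x_px + row.rx) + 1, w)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        inside = ((yy - row.y_px) / row.ry) ** 2 + ((xx - row.x_px) / row.rx) ** 2 <= 1.0
        labels[y0:y1, x0:x1][inside] = row.cell_id
    if len(cells):
        counts = np.bincount(labels.ravel(), minlength=int(cells["cell_id"].max()) + 1)
        for row in cells.itertuples(index=False):
            if counts[row.cell_id] > 0:
                continue
            cy = int(np.clip(round(row.y_px), 0, h - 1))
            cx = int(np.clip(round(row.x_px), 0, w - 1))
            for radius in range(0, max(h, w)):
                claimed = False
                for dy in range(-radius, radius + 1):
                    for dx in range(-radius, radius + 1):
                        y, x = cy + dy, cx + dx
                        if not (0 <= y < h and 0 <= x < w):
                            continue
                        owner = labels[y, x]
                        if owner == 0 or counts[owner] > 1:
                            counts[owner] -= 1
                            labels[y, x] = row.cell_id
                            counts[row.cell_id] += 1
                            claimed = True
                            break
                    if claimed:
                        break
                if claimed:
                    break
    return labels


def _render_stack(
    spec: TissueSpec, cells: pd.DataFrame, labels: np.ndarray, rng: np.random.Generator
) -> ImageStack:
    markers = spec.markers
    h, w = spec.image_shape
    pixels = rng.poisson(spec.background_rate, size=(len(markers), h, w)).astype(float)
    for row in cells.itertuples(index=False):
        member = labels == row.cell_id
        npx = int(member.sum())
        if npx == 0:
            continue
        profile = spec.subtype_profiles[row.subtype]
        for ci, marker in enumerate(markers):
            mean, disp = profile[marker]
            if mean <= 0:
                continue
            if disp > 0:
                shape_param = 1.0 / (disp * disp)
                cell_mean = mean * rng.gamma(shape_param, 1.0 / shape_param)
            else:
                cell_mean = mean
            pixels[ci][member] = rng.poisson(cell_mean, size=npx)
    panel = [(f"M{i:02d}", m) for i, m in enumerate(markers)]
    return ImageStack(pixels=pixels, panel=panel, pixel_size_um=1.0)


def generate_tissue(
    spec: TissueSpec, render: bool = True, rng: np.random.Generator | None = None
) -> tuple[ImageStack | None, LabelMask, GroundTruth]:
    """Generate one synthetic tissue sample.

    Returns the rendered multichannel stack (``None`` when ``render`` is
    off), the true instance mask, and the ground truth table.  Deterministic
    given ``spec.seed``.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    if spec.n_cells == 0:
        labels = np.zeros(spec.image_shape, dtype=np.int32)
        empty = pd.DataFrame(columns=["cell_id", "subtype", "x_px", "y_px", "rx", "ry"])
        stack = _render_stack(spec, empty, labels, rng) if render else None
        return stack, LabelMask(labels, provenance="synthetic"), GroundTruth(cells=empty)
    cells, _ = _place_cells(spec, rng)
    labels = _rasterize(cells, spec.image_shape)
    truth = GroundTruth(cells=cells)
    stack = _render_stack(spec, cells, labels, rng) if render else None
    return stack, LabelMask(labels, provenance="synthetic"), truth


def apply_spillover(stack: ImageStack, spillover_matrix: np.ndarray) -> ImageStack:
    """Forward spillover model: observed pixel vector = S.T @ true vector.

    The inverse (compensation) lives in :mod:`imctme.preprocess`; this
    forward map exists so the round trip can be tested on known stacks.
    """
    S = np.asarray(spillover_matrix, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("spillover matrix must be square")
    if S.shape[0] != stack.n_channels:
        raise ValueError(
            f"spillover matrix is {S.shape[0]}x{S.shape[1]} but stack has "
            f"{stack.n_channels} channels"
        )
    if (S < 0).any() or (np.diag(S) <= 0).any():
        raise ValueError("spillover matrix must be non-negative with positive diagonal")
    c = stack.n_channels
    mixed = np.einsum("st,shw->thw", S, stack.pixels)
    return ImageStack(pixels=mixed, panel=list(stack.panel), pixel_size_um=stack.pixel_size_um)


def _apply_interaction_effects(
    cells: pd.DataFrame,
    effects: Mapping[tuple[str, str], float],
    shape: tuple[int, int],
    centers: np.ndarray,
    near_radius: float,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, list[tuple]]:
    """Co-localize m-cells with j-cells near the tumor nests.

    For each planted pair (m, j) a fraction ``strength`` of the m-cells
    that already sit near a cluster center is re-placed 4-10 px from a
    randomly chosen nearby j-cell.  This is a short-range rearrangement:
    the tumor-enriched region and the subtype counts inside it barely
    move, but the m-j adjacency (hence Avg.C) rises.
    """
    applied = []
    cells = cells.copy()
    h, w = shape

    def near_center(idx: np.ndarray, radius: float) -> np.ndarray:
        if len(centers) == 0 or len(idx) == 0:
            return idx[:0]
        pts = cells.loc[idx, ["y_px", "x_px"]].to_numpy()
        d = np.min(
            np.linalg.norm(pts[:, None, :] - centers[None, :, :], axis=2), axis=1
        )
        return idx[d <= radius]

    for (m, j), strength in effects.items():
        if strength <= 0:
            continue
        m_near = near_center(cells.index[cells["subtype"] == m].to_numpy(), near_radius)
        # anchors come from the dense nest core so the moved cells land where
        # j-neighbors are plentiful
        j_near = near_center(
            cells.index[cells["subtype"] == j].to_numpy(), 0.35 * near_radius
        )
        if len(m_near) == 0 or len(j_near) == 0:
            continue
        n_move = int(round(strength * len(m_near)))
        move = rng.choice(m_near, size=n_move, replace=False)
        anchors = rng.choice(j_near, size=n_move, replace=True)
        ang = rng.uniform(0, 2 * math.pi, size=n_move)
        dist = rng.uniform(3.0, 8.0, size=n_move)  # well inside the 20 um rule
        cells.loc[move, "y_px"] = np.clip(
            cells.loc[anchors, "y_px"].to_numpy() + dist * np.sin(ang), 1, h - 2
        )
        cells.loc[move, "x_px"] = np.clip(
            cells.loc[anchors, "x_px"].to_numpy() + dist * np.cos(ang), 1, w - 2
        )
        applied.append(("interaction", m, j, strength))
    return cells, applied


def generate_cohort(
    tissue_spec: TissueSpec, cohort_spec: CohortSpec, render: bool = False
) -> list[CohortSample]:
    """Generate an LTS/STS cohort with planted class effects.

    Density effects shift subtype mixing weights between the classes
    (half the effect up in LTS, half down in STS, then renormalized).
    Interaction effects co-localize cell pairs in LTS samples only.
    Rendering full pixel stacks is optional; the ground-truth cell tables
    are always produced and are sufficient for the spatial feature stages.
    """
    base_weights = tissue_spec.weights()
    order = [("LTS", i) for i in range(cohort_spec.n_samples_per_class["LTS"])] + [
        ("STS", i) for i in range(cohort_spec.n_samples_per_class["STS"])
    ]
    samples: list[CohortSample] = []
    for cls, idx in order:
        # per-(class, index) child seeds: growing a cohort never perturbs
        # the samples already generated
        child = np.random.SeedSequence([cohort_spec.seed, 0 if cls == "LTS" else 1, idx])
        rng = np.random.default_rng(child)
        weights = dict(base_weights)
        registry: list[tuple] = []
        for subtype, eff in cohort_spec.planted_density_effects.items():
            delta = eff / 2 if cls == "LTS" else -eff / 2
            weights[subtype] = max(weights.get(subtype, 0.0) + delta, 1e-6)
            registry.append(("density", subtype, eff))
        total = sum(weights.values())
        weights = {s: v / total for s, v in weights.items()}
        spec = TissueSpec(
            image_shape=tissue_spec.image_shape,
            subtype_profiles=tissue_spec.subtype_profiles,
            subtype_weights=weights,
            tumor_subtypes=tissue_spec.tumor_subtypes,
            n_cluster_centers=tissue_spec.n_cluster_centers,
            cluster_spread_px=tissue_spec.cluster_spread_px,
            cell_radius_range=tissue_spec.cell_radius_range,
            n_cells=tissue_spec.n_cells,
            background_rate=tissue_spec.background_rate,
            min_spacing_px=tissue_spec.min_spacing_px,
            seed=tissue_spec.seed,
        )
        cells, centers = _place_cells(spec, rng)
        if cls == "LTS" and cohort_spec.planted_interaction_effects:
            cells, applied = _apply_interaction_effects(
                cells,
                cohort_spec.planted_interaction_effects,
                spec.image_shape,
                centers,
                2.0 * spec.cluster_spread_px,
                rng,
            )
            registry.extend(applied)
        else:
            registry.extend(
                ("interaction", m, j, s)
                for (m, j), s in cohort_spec.planted_interaction_effects.items()
            )
        labels = _rasterize(cells, spec.image_shape)
        stack = _render_stack(spec, cells, labels, rng) if render else None
        truth = GroundTruth(cells=cells, class_label=cls, registry=registry)
        lo, hi = cohort_spec.survival_months[cls]
        mean_age, sd_age = cohort_spec.age_distribution[cls]
        survival = {
            "sample_id": f"{cls}_{idx:02d}",
            "os_months": float(rng.uniform(lo, hi)),
            "event": 1 if cls == "STS" else int(rng.random() < 0.5),
            "class": cls,
            "age": float(rng.normal(mean_age, sd_age)),
        }
        samples.append(
            CohortSample(
                sample_id=survival["sample_id"],
                stack=stack,
                mask=LabelMask(labels, provenance="synthetic"),
                truth=truth,
                survival=survival,
            )
        )
    return samples


def cohort_cell_table(cohort: Sequence[CohortSample], pixel_size_um: float = 1.0) -> pd.DataFrame:
    """Stack all ground-truth cells into one table with micron coordinates.

    The result has the column contract the spatial-features stage expects
    (``sample_id, cell_id, x_um, y_um, subtype``), so planted cohorts can be
    fed to it directly, bypassing segmentation and phenotyping.
    """
    frames = []
    for s in cohort:
        df = s.truth.cells[["cell_id", "subtype"]].copy()
        df.insert(0, "sample_id", s.sample_id)
        df["x_um"] = s.truth.cells["x_px"] * pixel_size_um
        df["y_um"] = s.truth.cells["y_px"] * pixel_size_um
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def cohort_survival_table(cohort: Sequence[CohortSample]) -> pd.DataFrame:
    return pd.DataFrame([s.survival for s in cohort])


def generate_expression(
    densities: pd.Series | Mapping[str, Mapping[str, float]],
    planted_corr: Mapping[str, tuple[str, float]],
    n_noise_genes: int = 100,
    seed: int = 0,
    n_genes_total: int | None = None,
) -> pd.DataFrame:
    """Expression matrix (genes x samples) with planted Spearman targets.

    ``densities`` is a samples x subtypes DataFrame (or mapping) of cell
    densities; each planted gene names a subtype and a target Spearman r.
    Genes with ``|r| = 1`` are exact monotone transforms of the density;
    intermediate targets mix the density's normal scores with independent
    noise at the weight that gives the requested rank correlation in
    expectation.  Remaining rows are independent noise genes.
    """
    dens = pd.DataFrame(densities)
    n_samples = len(dens)
    for gene, (subtype, r) in planted_corr.items():
        if abs(r) > 1:
            raise ValueError(f"target Spearman r for {gene!r} must satisfy |r| <= 1")
        if subtype not in dens.columns:
            raise ValueError(f"planted gene {gene!r} names unknown subtype {subtype!r}")
    if n_genes_total is not None and len(planted_corr) > n_genes_total:
        raise ValueError(
            f"{len(planted_corr)} planted genes exceed requested total of {n_genes_total}"
        )
    if n_genes_total is not None:
        n_noise_genes = n_genes_total - len(planted_corr)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x0E]))
    rows = {}
    for gene, (subtype, r) in planted_corr.items():
        d = dens[subtype].to_numpy(dtype=float)
        if abs(r) == 1.0:
            expr = np.sign(r) * np.log1p(d - d.min())  # monotone transform
        else:
            ranks = pd.Series(d).rank(method="average").to_numpy()
            z = (ranks - ranks.mean()) / max(ranks.std(), 1e-12)
            noise = rng.standard_normal(n_samples)
            # Calibrate the mixing weight against the realized sample: the
            # sample Spearman of w*z + sqrt(1-w^2)*noise is monotone in w,
            # so bisection pins it near the target despite rank noise.
            def sample_r(w: float) -> float:
                mix = w * z + math.sqrt(max(1 - w * w, 0.0)) * noise
                return float(scipy.stats.spearmanr(mix, d).statistic)

            lo_w, hi_w = -1.0, 1.0
            for _ in range(40):
                mid = 0.5 * (lo_w + hi_w)
                if sample_r(mid) < r:
                    lo_w = mid
                else:
                    hi_w = mid
            w = 0.5 * (lo_w + hi_w)
            expr = w * z + math.sqrt(max(1 - w * w, 0.0)) * noise
        rows[gene] = expr + 8.0  # shift into a typical log-expression range
    for i in range(n_noise_genes):
        rows[f"noise_{i:04d}"] = rng.normal(8.0, 1.0, size=n_samples)
    return pd.DataFrame(rows, index=dens.index).T


def default_tissue_spec(seed: int = 0) -> TissueSpec:
    """Six-subtype tissue with two tumor subtypes, one stromal and three
    immune populations, on a 300 x 300 px frame with ~250 cells.

    Marker means are well separated between subtypes (roughly 5-30 counts on
    the defining markers vs <1 off-target) so that phenotyping is decidable;
    all subtypes share high nuclear channels for segmentation.
    """
    hi, mid, lo = 25.0, 10.0, 0.3
    d = 0.25  # per-cell CV
    markers = [
        "H3", "DNA191", "DNA193",
        "Keratin8_18", "SMA", "CD8a", "GranzymeB", "CD4", "CD45RO", "CD68", "CD73",
    ]

    def profile(**highs: float) -> dict[str, tuple[float, float]]:
        base = {m: (lo, d) for m in markers}
        for m in ("H3", "DNA191", "DNA193"):
            base[m] = (hi, d)
        for m, v in highs.items():
            base[m] = (v, d)
        return base

    profiles = {
        "tu_1": profile(Keratin8_18=hi),
        "tu_2": profile(Keratin8_18=hi, CD73=mid),
        "s_1": profile(SMA=hi),
        "CD8_4": profile(CD8a=hi, GranzymeB=mid),
        "CD4_4": profile(CD4=hi, CD45RO=mid),
        "ma_1": profile(CD68=hi),
    }
    weights = {"tu_1": 0.25, "tu_2": 0.20, "s_1": 0.20, "CD8_4": 0.10, "CD4_4": 0.10, "ma_1": 0.15}
    return TissueSpec(
        image_shape=(300, 300),
        subtype_profiles=profiles,
        subtype_weights=weights,
        tumor_subtypes=("tu_1", "tu_2"),
        n_cluster_centers=3,
        cluster_spread_px=30.0,
        cell_radius_range=(3.0, 5.0),
        n_cells=250,
        seed=seed,
    )


def default_cohort_spec(seed: int = 0, null: bool = False) -> CohortSpec:
    """21 LTS + 20 STS cohort; the planted effects mirror the direction of
    the headline biology (cytotoxic T-cell density and T-cell/tumor
    co-localization higher in long-term survivors).

    ``null=True`` removes every planted effect, for calibration runs.
    """
    if null:
        return CohortSpec(seed=seed)
    return CohortSpec(
        planted_density_effects={"CD8_4": 0.10},
        planted_interaction_effects={("CD8_4", "tu_1"): 0.6},
        seed=seed,
    )
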