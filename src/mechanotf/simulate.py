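"""Synthetic benchmarks with known ground truth.

Three generators emulate the pipeline's inputs:

* a PPI + TF->target network benchmark with a planted active cascade —
  an upstream hub protein wired by high-confidence edges to a subset of
  TFs whose targets carry elevated fold changes in both contrasts
  (up under load, down under ERK inhibition) on top of null background
  genes;
* DAPI-like nucleus images with controllable heterochromatin-focus
  count, contrast and peripheral bias;
* spheroid images with a dense core and cells scattered out to a
  controllable migration radius.

Every generator is a pure function of its parameters and seed, and each
returns the ground truth needed to score the downstream operations
(planted TFs and target sets, object masks, planted areas) without
re-deriving it.

Planted PPI path scores are drawn high (>= 800) while background edges
are uniform in [150, 700]: the cost structure favors — but does not
force — recovery of the planted cascade, so recovery tests are
informative rather than tautological.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from mechanotf.io import InteractionRecord, TFTargetRecord


@dataclass
class NetBenchParams:
    """Network-benchmark parameters.

    Sizes default to a desk-scale analog of the screen's inputs: a few
    dozen background proteins, a handful of regulators of which some are
    planted as active, and ~5 prized targets per planted TF (mirroring
    the study's 119-gene target list at reduced scale). Effect sizes
    default to |log2FC| around 2 for planted genes against a 0.3-SD null
    background, a typical strong-response contrast.
    """

    n_proteins: int = 40
    n_tfs: int = 6
    n_planted_tfs: int = 3
    n_targets_per_tf: int = 5
    n_background_genes: int = 200
    background_edge_density: float = 0.08
    planted_score_low: int = 800
    planted_score_high: int = 999
    background_score_low: int = 150
    background_score_high: int = 700
    planted_log2fc_mean: float = 2.0
    planted_log2fc_sd: float = 0.4
    noise_log2fc_sd: float = 0.3
    planted_padj_max: float = 1e-3
    padj_threshold: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.n_planted_tfs > self.n_tfs:
            raise ValueError("n_planted_tfs must be <= n_tfs")
        if not 0 < self.background_edge_density < 1:
            raise ValueError("background_edge_density must be in (0, 1)")
        if self.planted_score_low < self.background_score_high:
            raise ValueError("planted scores must exceed background scores")


@dataclass
class ImageBenchParams:
    """Image-benchmark parameters (16-bit intensity range to exercise
    bit-depth handling; confocal data are 12/16-bit)."""

    shape: tuple[int, int] = (256, 256)
    n_nuclei: int = 5
    nucleus_radius: tuple[int, int] = (16, 24)
    n_foci: int = 4
    focus_radius: tuple[int, int] = (2, 4)
    background_intensity: float = 8000.0
    focus_contrast: float = 3.0
    texture_sd: float = 600.0
    noise_sd: float = 200.0
    peripheral_bias: float = 0.5
    core_radius: int = 50
    migration_radius: int = 90
    n_cells: int = 60
    cell_radius: tuple[int, int] = (3, 5)
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.peripheral_bias <= 1:
            raise ValueError("peripheral_bias must be in [0, 1]")
        if self.migration_radius < self.core_radius:
            raise ValueError("migration_radius must be >= core_radius")


@dataclass
class GroundTruth:
    """Planted structure emitted alongside generated data."""

    planted_tfs: list[str] = field(default_factory=list)
    planted_targets: dict[str, list[str]] = field(default_factory=dict)
    cascade_edges: list[tuple[str, str]] = field(default_factory=list)
    hub: str | None = None
    nucleus_mask: np.ndarray | None = None
    focus_mask: np.ndarray | None = None
    focus_counts: dict[int, int] = field(default_factory=dict)
    spread_area: float | None = None
    core_area: float | None = None
    migrated_area: float | None = None

    @property
    def all_planted_targets(self) -> set[str]:
        return {g for ts in self.planted_targets.values() for g in ts}


def generate_network_benchmark(
    params: NetBenchParams | None = None,
) -> tuple[list[InteractionRecord], list[TFTargetRecord], pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate (ppi, tf_targets, up-DE table, down-DE table, truth).

    The planted cascade is hub --(high-score PPI)--> planted TFs
    --(TF->target)--> planted target genes; planted targets are drawn
    up in the load contrast and down in the inhibitor contrast with
    padj below threshold, the hub and planted TFs are load-upregulated
    (so they carry node values), and everything else is null noise.
    """
    params = params or NetBenchParams()
    params.validate()
    rng = np.random.default_rng(params.seed)

    hub = "HUB"
    proteins = [f"P{i:03d}" for i in range(params.n_proteins)]
    tfs = [f"TF{i:02d}" for i in range(params.n_tfs)]
    planted_tfs = tfs[: params.n_planted_tfs]
    background_genes = [f"G{i:03d}" for i in range(params.n_background_genes)]

    truth = GroundTruth(planted_tfs=list(planted_tfs), hub=hub)

    # --- TF -> target table: planted TFs get dedicated planted targets,
    # every TF additionally regulates some background genes.
    tf_records: list[TFTargetRecord] = []
    next_target = 0
    for tf in planted_tfs:
        targets = []
        for _ in range(params.n_targets_per_tf):
            targets.append(f"T{next_target:03d}")
            next_target += 1
        truth.planted_targets[tf] = targets
        for t in targets:
            tf_records.append(TFTargetRecord(tf, t))
            truth.cascade_edges.append((tf, t))
    for tf in tfs:
        n_bg = int(rng.integers(3, 8))
        for t in rng.choice(background_genes, size=n_bg, replace=False):
            tf_records.append(TFTargetRecord(tf, str(t)))
    planted_targets = sorted(truth.all_planted_targets)

    # --- PPI: high-score planted path hub--TF, background Erdos-Renyi.
    ppi: dict[tuple[str, str], int] = {}

    def add_edge(a: str, b: str, score: int) -> None:
        key = (a, b) if a < b else (b, a)
        ppi[key] = max(ppi.get(key, 0), int(score))

    for tf in planted_tfs:
        add_edge(hub, tf, rng.integers(params.planted_score_low, params.planted_score_high + 1))
        truth.cascade_edges.append((hub, tf))
    ppi_genes = [hub] + proteins + tfs
    for i, a in enumerate(ppi_genes):
        for b in ppi_genes[i + 1 :]:
            if (min(a, b), max(a, b)) in ppi:
                continue
            if rng.random() < params.background_edge_density:
                add_edge(a, b, rng.integers(params.background_score_low,
                                            params.background_score_high + 1))
    # keep the benchmark graph connected: chain any isolated gene in
    for g in ppi_genes:
        if not any(g in k for k in ppi):
            other = hub if g != hub else proteins[0]
            add_edge(g, other, rng.integers(params.background_score_low,
                                            params.background_score_high + 1))
    ppi_records = [InteractionRecord(a, b, s) for (a, b), s in sorted(ppi.items())]

    # --- DE tables.
    def planted_fc(sign: float, size: int) -> np.ndarray:
        return sign * np.abs(
            rng.normal(params.planted_log2fc_mean, params.planted_log2fc_sd, size)
        )

    def planted_padj(size: int) -> np.ndarray:
        return rng.uniform(1e-8, params.planted_padj_max, size)

    up_rows, down_rows = [], []
    # planted targets: up under load, down under the inhibitor. A zero
    # planted effect size means no signal: the benchmark degenerates to
    # a pure null and the planted genes are drawn like background.
    if params.planted_log2fc_mean != 0:
        up_rows += list(zip(planted_targets,
                            planted_fc(+1, len(planted_targets)),
                            planted_padj(len(planted_targets))))
        down_rows += list(zip(planted_targets,
                              planted_fc(-1, len(planted_targets)),
                              planted_padj(len(planted_targets))))
    else:
        for rows in (up_rows, down_rows):
            rows += list(zip(planted_targets,
                             rng.normal(0.0, params.noise_log2fc_sd,
                                        len(planted_targets)),
                             rng.uniform(0, 1, len(planted_targets))))
    # hub and planted TFs: load-upregulated (node values for the solver)
    drivers = [hub] + planted_tfs
    up_rows += list(zip(drivers,
                        np.abs(rng.normal(1.5, 0.3, len(drivers))),
                        planted_padj(len(drivers))))
    # background genes (plus non-planted TFs and proteins): null noise
    null_up = background_genes + tfs[params.n_planted_tfs:] + proteins
    up_rows += list(zip(null_up,
                        rng.normal(0.0, params.noise_log2fc_sd, len(null_up)),
                        rng.uniform(0, 1, len(null_up))))
    null_down = background_genes + tfs + proteins + [hub]
    down_rows += list(zip(null_down,
                          rng.normal(0.0, params.noise_log2fc_sd, len(null_down)),
                          rng.uniform(0, 1, len(null_down))))

    up = pd.DataFrame(up_rows, columns=["gene", "log2fc", "padj"])
    down = pd.DataFrame(down_rows, columns=["gene", "log2fc", "padj"])

    # Condition the null: a background gene that lands significant-up
    # under load AND significant-down under the inhibitor purely by
    # chance would blur the planted prized set, so its null draw is
    # rejected and resampled. This keeps the ground-truth target set
    # exactly the planted one at any seed.
    thr = params.padj_threshold
    up_sig = set(up.loc[(up["log2fc"] > 0) & (up["padj"] < thr), "gene"])
    down_idx = down.set_index("gene")
    for gene in sorted(up_sig - truth.all_planted_targets):
        if gene not in down_idx.index:
            continue
        while (down_idx.at[gene, "log2fc"] < 0 and down_idx.at[gene, "padj"] < thr):
            down_idx.at[gene, "log2fc"] = rng.normal(0.0, params.noise_log2fc_sd)
            down_idx.at[gene, "padj"] = rng.uniform(0, 1)
    down = down_idx.reset_index()[["gene", "log2fc", "padj"]]
    return ppi_records, tf_records, up, down, truth


# ---------------------------------------------------------------------------
# images


def _ellipse_mask(shape, center, radii, angle) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    y, x = rr - center[0], cc - center[1]
    ca, sa = np.cos(angle), np.sin(angle)
    u = (x * ca + y * sa) / radii[1]
    v = (-x * sa + y * ca) / radii[0]
    return u**2 + v**2 <= 1.0


def _disk_mask(shape, center, radius) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def generate_nucleus_image(
    params: ImageBenchParams | None = None,
) -> tuple[np.ndarray, GroundTruth]:
    """Render elliptical DAPI-like nuclei with bright heterochromatin
    foci and return the image with its ground-truth masks.

    Focus centers fall in the peripheral third of the ellipse with
    probability ``peripheral_bias``, otherwise in the core. With
    ``texture_sd = noise_sd = 0`` and ``n_foci = 0`` nuclei are exactly
    uniform.
    """
    params = params or ImageBenchParams()
    params.validate()
    rng = np.random.default_rng(params.seed)
    from scipy import ndimage as ndi

    shape = params.shape
    img = np.zeros(shape, dtype=float)
    nucleus_mask = np.zeros(shape, dtype=int)
    focus_mask = np.zeros(shape, dtype=int)
    truth = GroundTruth(nucleus_mask=nucleus_mask, focus_mask=focus_mask)

    placed = []
    attempts = 0
    nid = 0
    while nid < params.n_nuclei and attempts < 500:
        attempts += 1
        r_a = rng.integers(params.nucleus_radius[0], params.nucleus_radius[1] + 1)
        r_b = rng.integers(params.nucleus_radius[0], params.nucleus_radius[1] + 1)
        margin = max(r_a, r_b) + 4
        cy = rng.integers(margin, shape[0] - margin)
        cx = rng.integers(margin, shape[1] - margin)
        if any((cy - y) ** 2 + (cx - x) ** 2 < (max(r_a, r_b) + r + 6) ** 2
               for y, x, r in placed):
            continue
        angle = rng.uniform(0, np.pi)
        mask = _ellipse_mask(shape, (cy, cx), (r_a, r_b), angle)
        nid += 1
        placed.append((cy, cx, max(r_a, r_b)))
        nucleus_mask[mask] = nid
        img[mask] = params.background_intensity
        if params.texture_sd > 0:
            texture = rng.normal(0, params.texture_sd, shape)
            texture = ndi.gaussian_filter(texture, 2.0)
            img[mask] += texture[mask]

        # plant foci: peripheral (outer third of the radial coordinate)
        # with probability peripheral_bias, core otherwise
        n_placed_foci = 0
        focus_attempts = 0
        while n_placed_foci < params.n_foci and focus_attempts < 200:
            focus_attempts += 1
            fr = rng.integers(params.focus_radius[0], params.focus_radius[1] + 1)
            peripheral = rng.random() < params.peripheral_bias
            rad_frac = rng.uniform(0.82, 0.95) if peripheral else rng.uniform(0.0, 0.4)
            theta = rng.uniform(0, 2 * np.pi)
            # position along the ellipse axes at the chosen radial fraction
            ey = rad_frac * r_a * np.sin(theta)
            ex = rad_frac * r_b * np.cos(theta)
            fy = cy + ey * np.cos(angle) - ex * np.sin(angle)
            fx = cx + ey * np.sin(angle) + ex * np.cos(angle)
            fmask = _disk_mask(shape, (fy, fx), fr)
            fmask &= mask
            # keep foci separated so they stay distinct connected components
            touching = ndi.binary_dilation(fmask, iterations=2)
            if fmask.sum() < 3 or (focus_mask[touching] > 0).any():
                continue
            img[fmask] = params.background_intensity * params.focus_contrast
            focus_mask[fmask] = focus_mask.max() + 1
            n_placed_foci += 1
        truth.focus_counts[nid] = n_placed_foci

    if params.noise_sd > 0:
        img += rng.normal(0, params.noise_sd, shape)
    img = np.clip(img, 0, 65535)
    return img.astype(np.uint16).astype(float), truth


def generate_spheroid_image(
    params: ImageBenchParams | None = None,
) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Render a spheroid: dense core disc plus small cell blobs
    scattered at radii up to ``migration_radius``.

    Returns (dapi, actin, truth); the actin channel marks the same
    structures with slightly broader cell footprints. Ground-truth
    spread area is the area of the union of core and cell masks.
    """
    params = params or ImageBenchParams()
    params.validate()
    rng = np.random.default_rng(params.seed)
    side = int(2 * params.migration_radius + 60)
    shape = (side, side)
    center = (side // 2, side // 2)

    core = _disk_mask(shape, center, params.core_radius)
    cells = np.zeros(shape, dtype=bool)
    actin_cells = np.zeros(shape, dtype=bool)
    if params.migration_radius > params.core_radius:
        for _ in range(params.n_cells):
            rad = rng.uniform(params.core_radius, params.migration_radius)
            theta = rng.uniform(0, 2 * np.pi)
            cy = center[0] + rad * np.sin(theta)
            cx = center[1] + rad * np.cos(theta)
            cr = rng.integers(params.cell_radius[0], params.cell_radius[1] + 1)
            cells |= _disk_mask(shape, (cy, cx), cr)
            actin_cells |= _disk_mask(shape, (cy, cx), cr + 2)

    union = core | cells
    truth = GroundTruth(
        spread_area=float(union.sum()),
        core_area=float(core.sum()),
        migrated_area=float((cells & ~core).sum()),
    )
    high = 30000.0
    dapi = np.where(union, high, 500.0)
    actin = np.where(core | actin_cells, high, 500.0)
    if params.noise_sd > 0:
        dapi = dapi + rng.normal(0, params.noise_sd, shape)
        actin = actin + rng.normal(0, params.noise_sd, shape)
    dapi = np.clip(dapi, 0, 65535).astype(np.uint16).astype(float)
    actin = np.clip(actin, 0, 65535).astype(np.uint16).astype(float)
    return dapi, actin, truth
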