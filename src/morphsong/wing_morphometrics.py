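"""Landmark I/O, generalized Procrustes analysis, and wing measurements.

The right forewing is summarized by 14 ordered landmarks (1-based indexing
throughout the interface, matching the digitizing convention). Two derived
structure sizes are measured on *calibrated raw* coordinates, before any
Procrustes superimposition, because superimposition deliberately removes
size: harp width is the x-axis distance between landmarks 5 and 14, and
mirror size is the centroid size of the mirror-perimeter landmarks 6-11.
Shape variation is summarized by PCA of GPA-aligned coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "LandmarkConfiguration",
    "WingFeatures",
    "ProcrustesResult",
    "read_tps",
    "write_tps",
    "centroid_size",
    "harp_width",
    "mirror_size",
    "generalized_procrustes",
    "shape_pca",
    "extract_wing_features",
    "N_LANDMARKS",
    "HARP_LANDMARKS",
    "MIRROR_LANDMARKS",
]

N_LANDMARKS = 14
HARP_LANDMARKS = (5, 14)  # 1-based
MIRROR_LANDMARKS = (6, 7, 8, 9, 10, 11)  # 1-based perimeter of the mirror


@dataclass(frozen=True)
class LandmarkConfiguration:
    """14 ordered (x, y) landmarks for one wing.

    Coordinates follow the tpsDIG convention: origin bottom-left, y
    increasing upward. ``scale_mm_per_unit`` converts digitizer units to mm;
    1.0 means coordinates are already calibrated.
    """

    points: np.ndarray
    individual_id: str = ""
    scale_mm_per_unit: float | None = None

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.shape != (N_LANDMARKS, 2):
            raise ValueError(
                f"{self.individual_id or 'configuration'}: expected "
                f"{N_LANDMARKS} (x, y) landmarks, got shape {pts.shape}"
            )
        if not np.all(np.isfinite(pts)):
            raise ValueError(f"{self.individual_id}: non-finite landmark coordinates")
        # duplicate points break rotation fitting and indicate digitizing errors
        if len(np.unique(pts, axis=0)) != N_LANDMARKS:
            raise ValueError(f"{self.individual_id}: two landmarks coincide exactly")
        object.__setattr__(self, "points", pts)

    def calibrated(self) -> np.ndarray:
        scale = 1.0 if self.scale_mm_per_unit is None else self.scale_mm_per_unit
        return self.points * scale

    def landmark(self, index_1based: int) -> np.ndarray:
        if not 1 <= index_1based <= N_LANDMARKS:
            raise IndexError(f"landmark index {index_1based} outside 1..{N_LANDMARKS}")
        return self.points[index_1based - 1]


@dataclass(frozen=True)
class WingFeatures:
    harp_width: float
    mirror_size: float | None  # None when the mirror is absent
    scraper_present: bool
    mirror_present: bool
    file_gaps_present: bool
    individual_id: str = ""
    shape_scores: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.harp_width <= 0:
            raise ValueError(f"{self.individual_id}: harp_width must be positive")
        if self.mirror_size is not None and not self.mirror_present:
            raise ValueError(
                f"{self.individual_id}: mirror_size given but mirror_present is False"
            )

    def to_dict(self) -> dict:
        d = {
            "individual_id": self.individual_id,
            "harp_width": self.harp_width,
            "mirror_size": np.nan if self.mirror_size is None else self.mirror_size,
            "scraper_present": int(self.scraper_present),
            "mirror_present": int(self.mirror_present),
            "file_gaps_present": int(self.file_gaps_present),
        }
        for i, s in enumerate(self.shape_scores, start=1):
            d[f"shape_pc{i}"] = s
        return d


@dataclass(frozen=True)
class ProcrustesResult:
    aligned: np.ndarray  # (n, 14, 2), centered, unit centroid size
    mean_shape: np.ndarray  # (14, 2)
    centroid_sizes: np.ndarray  # (n,) original sizes
    iterations: int
    final_change: float
    ids: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# TPS I/O (tpsDIG2 dialect: LM=, coordinate lines, optional IMAGE=/ID=/SCALE=)


def read_tps(path: str | Path) -> list[LandmarkConfiguration]:
    """Parse a TPS landmark file into per-specimen configurations.

    Coordinates are multiplied by SCALE when a SCALE= record is present.
    Every specimen must carry exactly 14 landmarks.
    """
    path = Path(path)
    specimens: list[LandmarkConfiguration] = []
    lm_expected: int | None = None
    coords: list[tuple[float, float]] = []
    spec_id: str | None = None
    scale: float | None = None
    start_line = 0

    def flush(line_no: int) -> None:
        nonlocal lm_expected, coords, spec_id, scale
        if lm_expected is None:
            return
        sid = spec_id if spec_id is not None else f"specimen_{len(specimens) + 1}"
        if lm_expected != N_LANDMARKS:
            raise ValueError(
                f"{path}:{start_line}: specimen {sid!r} declares LM={lm_expected}; "
                f"exactly {N_LANDMARKS} landmarks are required"
            )
        if len(coords) != lm_expected:
            raise ValueError(
                f"{path}:{line_no}: specimen {sid!r} has {len(coords)} coordinate "
                f"lines but declares LM={lm_expected}"
            )
        pts = np.asarray(coords, dtype=float)
        if scale is not None:
            pts = pts * scale
        specimens.append(LandmarkConfiguration(pts, individual_id=sid))
        lm_expected, coords, spec_id, scale = None, [], None, None

    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            upper = line.upper()
            if upper.startswith("LM="):
                flush(line_no)
                start_line = line_no
                try:
                    lm_expected = int(line.split("=", 1)[1])
                except ValueError as exc:
                    raise ValueError(f"{path}:{line_no}: malformed LM record") from exc
            elif upper.startswith("ID="):
                spec_id = line.split("=", 1)[1].strip()
            elif upper.startswith("IMAGE="):
                if spec_id is None:
                    spec_id = Path(line.split("=", 1)[1].strip()).stem
            elif upper.startswith("SCALE="):
                try:
                    scale = float(line.split("=", 1)[1])
                except ValueError as exc:
                    raise ValueError(f"{path}:{line_no}: malformed SCALE record") from exc
            else:
                parts = line.split()
                if lm_expected is None or len(parts) != 2:
                    raise ValueError(f"{path}:{line_no}: malformed record {line!r}")
                try:
                    coords.append((float(parts[0]), float(parts[1])))
                except ValueError as exc:
                    raise ValueError(
                        f"{path}:{line_no}: non-numeric coordinate {line!r}"
                    ) from exc
    flush(line_no=-1)
    return specimens


def write_tps(path: str | Path, configs: list[LandmarkConfiguration]) -> None:
    with open(path, "w") as fh:
        for cfg in configs:
            fh.write(f"LM={N_LANDMARKS}\n")
            for x, y in cfg.points:
                fh.write(f"{x:.10g} {y:.10g}\n")
            if cfg.individual_id:
                fh.write(f"ID={cfg.individual_id}\n")
            if cfg.scale_mm_per_unit is not None:
                fh.write(f"SCALE={cfg.scale_mm_per_unit:.10g}\n")


def read_flags(path: str | Path) -> pd.DataFrame:
    """Per-specimen categorical structure scores (0/1 columns)."""
    df = pd.read_csv(path)
    required = {"individual_id", "scraper", "mirror", "file_gaps"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: flags CSV missing columns {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# Measurements


def centroid_size(points) -> float:
    """Square root of summed squared distances of points to their centroid."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 2:
        raise ValueError(f"need >= 2 (x, y) points, got shape {pts.shape}")
    centered = pts - pts.mean(axis=0)
    size = float(np.sqrt(np.sum(centered**2)))
    if size == 0.0:
        raise ValueError("degenerate configuration: all points identical")
    return size


def harp_width(config: LandmarkConfiguration) -> float:
    """|x5 - x14| on calibrated raw coordinates (pre-Procrustes)."""
    pts = config.calibrated()
    i, j = HARP_LANDMARKS
    width = abs(float(pts[i - 1, 0] - pts[j - 1, 0]))
    if width == 0.0:
        warnings.warn(
            f"{config.individual_id}: landmarks {i} and {j} share an x "
            f"coordinate; harp width is degenerate (0)",
            stacklevel=2,
        )
    return width


def mirror_size(config: LandmarkConfiguration) -> float:
    """Centroid size of the mirror-perimeter landmarks 6-11 (calibrated)."""
    pts = config.calibrated()
    idx = [k - 1 for k in MIRROR_LANDMARKS]
    return centroid_size(pts[idx])


# ---------------------------------------------------------------------------
# Generalized Procrustes analysis


def _center_and_scale(pts: np.ndarray) -> tuple[np.ndarray, float]:
    centered = pts - pts.mean(axis=0)
    size = np.sqrt(np.sum(centered**2))
    if size == 0:
        raise ValueError("degenerate configuration: zero centroid size")
    return centered / size, float(size)


def _optimal_rotation(shape: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Least-squares rotation (no reflection) taking ``shape`` onto ``target``."""
    u, _, vt = np.linalg.svd(target.T @ shape)
    d = np.sign(np.linalg.det(u @ vt))
    correction = np.diag([1.0, d])
    return (u @ correction @ vt).T


def generalized_procrustes(
    configs: list[LandmarkConfiguration],
    tol: float = 1e-10,
    max_iter: int = 100,
) -> ProcrustesResult:
    """Iterative GPA: remove translation, scale, and rotation.

    Every configuration is centered and scaled to unit centroid size, then
    rotated to the current mean shape; the mean is re-estimated until its
    change falls below ``tol``. Full ordinary least-squares superimposition
    (no sliding semilandmarks).
    """
    if len(configs) < 2:
        raise ValueError("GPA needs at least two configurations")
    shapes, sizes = [], []
    for cfg in configs:
        try:
            shape, size = _center_and_scale(cfg.calibrated())
        except ValueError as exc:
            raise ValueError(f"{cfg.individual_id}: {exc}") from exc
        shapes.append(shape)
        sizes.append(size)
    aligned = np.stack(shapes)

    # align everything to the first specimen before the first mean estimate
    for i in range(1, len(aligned)):
        aligned[i] = aligned[i] @ _optimal_rotation(aligned[i], aligned[0])

    mean = aligned.mean(axis=0)
    change = np.inf
    iterations = 0
    for iterations in range(1, max_iter + 1):
        mean_unit = mean / np.sqrt(np.sum(mean**2))
        for i in range(len(aligned)):
            aligned[i] = aligned[i] @ _optimal_rotation(aligned[i], mean_unit)
        new_mean = aligned.mean(axis=0)
        change = float(np.sqrt(np.sum((new_mean - mean) ** 2)))
        mean = new_mean
        if change < tol:
            break
    return ProcrustesResult(
        aligned=aligned,
        mean_shape=mean,
        centroid_sizes=np.asarray(sizes),
        iterations=iterations,
        final_change=change,
        ids=tuple(cfg.individual_id for cfg in configs),
    )


def shape_pca(
    result: ProcrustesResult, n_components: int = 10
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Covariance-based PCA of aligned coordinates.

    Returns (scores, loadings, eigenvalues). Sign convention: the
    largest-magnitude loading of each component is positive, so scores are
    reproducible regardless of specimen ordering.
    """
    n = result.aligned.shape[0]
    flat = result.aligned.reshape(n, -1)
    flat = flat - flat.mean(axis=0)
    u, s, vt = np.linalg.svd(flat, full_matrices=False)
    eigvals = s**2 / (n - 1)
    k = min(n_components, len(s))
    loadings = vt[:k]
    scores = flat @ loadings.T
    for j in range(k):
        pivot = np.argmax(np.abs(loadings[j]))
        if loadings[j, pivot] < 0:
            loadings[j] = -loadings[j]
            scores[:, j] = -scores[:, j]
    return scores, loadings, eigvals[:k]


def extract_wing_features(
    config: LandmarkConfiguration,
    scraper_present: bool,
    mirror_present: bool,
    file_gaps_present: bool,
    shape_scores: tuple[float, ...] = (),
) -> WingFeatures:
    """Structure measurements + categorical flags for one wing.

    Mirror size is reported only when the mirror is present; its absence is
    an informative value, not an error.
    """
    return WingFeatures(
        individual_id=config.individual_id,
        harp_width=harp_width(config),
        mirror_size=mirror_size(config) if mirror_present else None,
        scraper_present=bool(scraper_present),
        mirror_present=bool(mirror_present),
        file_gaps_present=bool(file_gaps_present),
        shape_scores=tuple(float(s) for s in shape_scores),
    )


def wing_features_frame(features: list[WingFeatures]) -> pd.DataFrame:
    return pd.DataFrame([f.to_dict() for f in features])
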