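"""Landmark-based geometric morphometrics.

2D landmark configurations (default k = 4, the cervical-loop /
epithelium-junction suite used for the tissue-separation assay) are
superimposed by Generalized Procrustes Analysis (GPA): centring, scaling
to unit centroid size, and rotation-only orthogonal fits iterated to a
consensus.  Shape variation is then summarised by PCA on the aligned
coordinates, and digitizing measurement error is quantified with a
Goodall-style Procrustes ANOVA with permutation P-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LandmarkConfiguration",
    "LandmarkSeries",
    "ProcrustesResult",
    "read_tps",
    "write_tps",
    "centroid_size",
    "gpa",
    "shape_pca",
    "procrustes_anova",
]


@dataclass
class LandmarkConfiguration:
    """k x 2 landmark coordinates with specimen/frame/replicate labels."""

    coords: np.ndarray
    specimen: str = ""
    frame: int = 0
    replicate: int = 0
    image: str = ""

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coords must be (k, 2)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("landmark coordinates must be finite")

    @property
    def k(self) -> int:
        return self.coords.shape[0]


@dataclass
class LandmarkSeries:
    """Ordered frames of one digitized specimen/replicate."""

    frames: list[LandmarkConfiguration]
    specimen: str = ""
    replicate: int = 0

    def __post_init__(self):
        ks = {f.k for f in self.frames}
        if len(ks) > 1:
            raise ValueError("all frames must have the same landmark count")

    def configurations(self) -> list[LandmarkConfiguration]:
        return list(self.frames)


# ----------------------------------------------------------------------
# TPS I/O (tpsDig dialect: LM=, coordinate rows, optional IMAGE=, ID=)

def _format_label(c: LandmarkConfiguration) -> str:
    if c.image:
        return c.image
    return f"specimen={c.specimen};frame={c.frame};replicate={c.replicate}"


def _parse_label(image: str, config: LandmarkConfiguration) -> None:
    config.image = image
    parts = dict(
        p.split("=", 1) for p in image.split(";") if "=" in p
    ) if ";" in image or "=" in image else {}
    if {"specimen", "frame", "replicate"} <= set(parts):
        config.specimen = parts["specimen"]
        config.frame = int(parts["frame"])
        config.replicate = int(parts["replicate"])
        config.image = ""


def write_tps(path, configs: list[LandmarkConfiguration]) -> None:
    lines = []
    for n, c in enumerate(configs):
        lines.append(f"LM={c.k}")
        for x, y in c.coords:
            lines.append(f"{float(x)!r} {float(y)!r}")
        lines.append(f"IMAGE={_format_label(c)}")
        lines.append(f"ID={n}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_tps(path) -> list[LandmarkConfiguration]:
    configs: list[LandmarkConfiguration] = []
    coords: list[list[float]] = []
    expected = None
    current_meta: dict = {}

    def flush(line_no):
        nonlocal coords, expected, current_meta
        if expected is None:
            return
        if len(coords) != expected:
            raise ValueError(
                f"TPS record ending near line {line_no}: LM={expected} "
                f"but {len(coords)} coordinate rows"
            )
        c = LandmarkConfiguration(np.array(coords))
        if "image" in current_meta:
            _parse_label(current_meta["image"], c)
        configs.append(c)
        coords, expected, current_meta = [], None, {}

    with open(path) as fh:
        for line_no, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            upper = line.upper()
            if upper.startswith("LM="):
                flush(line_no)
                expected = int(line.split("=", 1)[1])
            elif upper.startswith("IMAGE="):
                current_meta["image"] = line.split("=", 1)[1]
            elif upper.startswith(("ID=", "SCALE=", "COMMENT=")):
                continue
            else:
                if expected is None:
                    raise ValueError(f"coordinate row before LM= at line {line_no}")
                parts = line.split()
                if len(parts) != 2:
                    raise ValueError(f"malformed coordinate row at line {line_no}")
                coords.append([float(parts[0]), float(parts[1])])
    flush("EOF")
    return configs


# ----------------------------------------------------------------------

def centroid_size(config: LandmarkConfiguration | np.ndarray) -> float:
    """Square root of the sum of squared landmark distances from their
    centroid."""
    x = config.coords if isinstance(config, LandmarkConfiguration) else np.asarray(config, float)
    centred = x - x.mean(axis=0)
    return float(np.sqrt((centred**2).sum()))


@dataclass
class ProcrustesResult:
    """GPA output: aligned configurations (centred, unit centroid size,
    optimally rotated), consensus mean shape (arithmetic average of the
    aligned set), per-configuration Procrustes distances to the mean,
    original centroid sizes, and the source labels."""

    aligned: np.ndarray  # (n, k, 2)
    mean_shape: np.ndarray  # (k, 2)
    distances: np.ndarray  # (n,)
    centroid_sizes: np.ndarray  # (n,)
    configs: list[LandmarkConfiguration] = field(default_factory=list)


def _best_rotation(x: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Rotation R (det +1, reflections excluded) minimising ||x R - target||."""
    h = x.T @ target
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    s = np.diag([1.0, d])
    return u @ s @ vt


def gpa(configs: list[LandmarkConfiguration] | np.ndarray, tol: float = 1e-12,
        max_iter: int = 200) -> ProcrustesResult:
    """Generalized Procrustes Analysis (full Procrustes: position, unit
    centroid-size scaling, rotation-only orientation removed).

    Iterates superimposition onto the current consensus until the mean
    shape moves by less than ``tol``.
    """
    if isinstance(configs, np.ndarray):
        configs = [LandmarkConfiguration(c) for c in configs]
    if len(configs) < 2:
        raise ValueError("GPA needs at least 2 configurations")
    ks = {c.k for c in configs}
    if len(ks) != 1:
        raise ValueError("all configurations must share the landmark count")
    x = np.stack([c.coords for c in configs]).astype(float)
    x -= x.mean(axis=1, keepdims=True)
    sizes = np.sqrt((x**2).sum(axis=(1, 2)))
    if np.any(sizes == 0):
        raise ValueError("degenerate configuration: all landmarks coincident")
    x /= sizes[:, None, None]

    mean = x[0].copy()
    mean /= np.sqrt((mean**2).sum())
    for _ in range(max_iter):
        for i in range(x.shape[0]):
            x[i] = x[i] @ _best_rotation(x[i], mean)
        new_mean = x.mean(axis=0)
        new_mean -= new_mean.mean(axis=0)
        norm = np.sqrt((new_mean**2).sum())
        new_mean /= norm
        if np.sqrt(((new_mean - mean) ** 2).sum()) < tol:
            mean = new_mean
            break
        mean = new_mean
    # final consensus: arithmetic average of the aligned set
    consensus = x.mean(axis=0)
    distances = np.sqrt(((x - consensus) ** 2).sum(axis=(1, 2)))
    return ProcrustesResult(
        aligned=x,
        mean_shape=consensus,
        distances=distances,
        centroid_sizes=sizes,
        configs=list(configs),
    )


@dataclass
class ShapePCA:
    components: np.ndarray  # (n_comp, 2k)
    variance_fractions: np.ndarray
    scores: np.ndarray  # (n, n_comp)
    mean_flat: np.ndarray  # (2k,)

    def score_of(self, shape: np.ndarray) -> np.ndarray:
        return (np.asarray(shape, float).ravel() - self.mean_flat) @ self.components.T


def shape_pca(result: ProcrustesResult) -> ShapePCA:
    """PCA of the Procrustes-aligned coordinates.

    Variance fractions sum to 1 and the consensus shape scores to the
    zero vector (it is the centring point).
    """
    n = result.aligned.shape[0]
    if n < 3:
        raise ValueError("shape PCA needs at least 3 configurations")
    flat = result.aligned.reshape(n, -1)
    mean_flat = flat.mean(axis=0)
    centred = flat - mean_flat
    u, s, vt = np.linalg.svd(centred, full_matrices=False)
    var = s**2
    total = var.sum()
    if total == 0:
        fractions = np.zeros_like(var)
    else:
        fractions = var / total
    scores = centred @ vt.T
    return ShapePCA(components=vt, variance_fractions=fractions, scores=scores,
                    mean_flat=mean_flat)


# ----------------------------------------------------------------------

@dataclass
class ProcrustesAnovaResult:
    shape_table: pd.DataFrame
    size_table: pd.DataFrame
    f_shape: float
    p_shape_perm: float
    p_shape_classical: float
    f_size: float
    p_size_perm: float
    p_size_classical: float


def _one_way_decomposition(values: np.ndarray, groups: np.ndarray,
                           units: np.ndarray):
    """SS decomposition of (n, p) rows into group effect, among-unit
    residual, and within-unit (replicate) error."""
    grand = values.mean(axis=0)
    ss_total = ((values - grand) ** 2).sum()
    uniq_groups = np.unique(groups)
    uniq_units = np.unique(units)
    group_means = {g: values[groups == g].mean(axis=0) for g in uniq_groups}
    unit_means = {u: values[units == u].mean(axis=0) for u in uniq_units}
    ss_effect = sum(
        ((group_means[g] - grand) ** 2).sum() * (groups == g).sum()
        for g in uniq_groups
    )
    ss_error = sum(
        ((values[units == u] - unit_means[u]) ** 2).sum() for u in uniq_units
    )
    ss_units = ss_total - ss_effect - ss_error
    return ss_total, ss_effect, ss_units, ss_error, len(uniq_groups), len(uniq_units)


def _anova_table(values: np.ndarray, groups: np.ndarray, units: np.ndarray,
                 dims: int, n_permutations: int, rng: np.random.Generator):
    n = values.shape[0]
    ss_total, ss_eff, ss_units, ss_err, n_g, n_u = _one_way_decomposition(
        values, groups, units)
    df_eff = (n_g - 1) * dims
    df_units = (n_u - n_g) * dims
    df_err = (n - n_u) * dims
    ms_eff = ss_eff / df_eff if df_eff else np.nan
    ms_units = ss_units / df_units if df_units else np.nan
    ms_err = ss_err / df_err if df_err else np.nan
    f = ms_eff / ms_err if ms_err and ms_err > 0 else np.inf
    p_classical = float(stats.f.sf(f, df_eff, df_err)) if np.isfinite(f) else 0.0

    # permutation of group labels at the unit level
    uniq_units = np.unique(units)
    unit_group = np.array([groups[units == u][0] for u in uniq_units])
    unit_mean = np.stack([values[units == u].mean(axis=0) for u in uniq_units])
    unit_n = np.array([(units == u).sum() for u in uniq_units])
    grand = values.mean(axis=0)

    def effect_ss(labels):
        out = 0.0
        for g in np.unique(labels):
            sel = labels == g
            w = unit_n[sel]
            gm = (unit_mean[sel] * w[:, None]).sum(axis=0) / w.sum()
            out += ((gm - grand) ** 2).sum() * w.sum()
        return out

    if not np.isfinite(f):
        # zero error MS: no permutation can beat the observed statistic
        p_perm = 1.0 / (n_permutations + 1)
    else:
        count = 0
        for _ in range(n_permutations):
            perm = rng.permutation(unit_group)
            if effect_ss(perm) / df_eff / ms_err >= f:
                count += 1
        p_perm = (1 + count) / (n_permutations + 1)

    table = pd.DataFrame(
        {
            "SS": [ss_eff, ss_units, ss_err, ss_total],
            "Df": [df_eff, df_units, df_err, df_eff + df_units + df_err],
            "MS": [ms_eff, ms_units, ms_err, np.nan],
            "F": [f, np.nan, np.nan, np.nan],
            "P_perm": [p_perm, np.nan, np.nan, np.nan],
            "P_classical": [p_classical, np.nan, np.nan, np.nan],
        },
        index=["effect", "units", "error", "total"],
    )
    return table, f, p_perm, p_classical


def procrustes_anova(configs: list[LandmarkConfiguration],
                     group_key: str = "specimen",
                     n_permutations: int = 999,
                     seed: int = 0) -> ProcrustesAnovaResult:
    """Goodall-style one-way Procrustes ANOVA plus a companion ANOVA on
    centroid size.

    Total Procrustes-aligned variation is decomposed into the main
    effect (default: specimen), among-unit residual (frames within
    specimen), and within-unit digitizing error (replicates of the same
    specimen/frame).  F = MS_effect / MS_error; P both by seeded label
    permutation at the unit level and from the classical F distribution
    (Procrustes data violate its assumptions, hence the permutation
    default).
    """
    groups = np.array([getattr(c, group_key) for c in configs])
    units = np.array([f"{c.specimen}|{c.frame}" for c in configs])
    if len(np.unique(groups)) < 2:
        raise ValueError("need at least 2 groups")
    counts = pd.Series(units).value_counts()
    if counts.min() < 2:
        raise ValueError("need at least 2 replicates per specimen/frame unit")
    res = gpa(configs)
    n, k, _ = res.aligned.shape
    dims = 2 * k - 4  # shape dimensions after removing position/size/rotation
    rng = np.random.default_rng(seed)
    shape_table, f_shape, p_perm, p_cls = _anova_table(
        res.aligned.reshape(n, -1), groups, units, dims, n_permutations, rng)
    size_table, f_size, p_size_perm, p_size_cls = _anova_table(
        res.centroid_sizes[:, None], groups, units, 1, n_permutations, rng)
    return ProcrustesAnovaResult(
        shape_table=shape_table,
        size_table=size_table,
        f_shape=f_shape,
        p_shape_perm=p_perm,
        p_shape_classical=p_cls,
        f_size=f_size,
        p_size_perm=p_size_perm,
        p_size_classical=p_size_cls,
    )


def average_replicates(configs: list[LandmarkConfiguration]) -> list[LandmarkConfiguration]:
    """Average digitizing replicates of the same specimen/frame into a
    single configuration (the downstream-analysis convention once the
    error check has passed)."""
    order: list[str] = []
    buckets: dict[str, list[LandmarkConfiguration]] = {}
    for c in configs:
        key = f"{c.specimen}|{c.frame}"
        if key not in buckets:
            buckets[key] = []
            order.append(key)
        buckets[key].append(c)
    out = []
    for key in order:
        grp = buckets[key]
        coords = np.mean([c.coords for c in grp], axis=0)
        out.append(LandmarkConfiguration(coords, specimen=grp[0].specimen,
                                         frame=grp[0].frame, replicate=-1))
    return out
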