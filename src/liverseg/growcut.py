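"""Seeded GrowCut cellular automaton.

Each pixel is a cell carrying a label ``l`` (0 = unlabeled, nonzero =
class; binary convention 1 = foreground, -1 = background), a strength
``theta`` in [0, 1] and a feature ``C`` (the gray value).  Seeds start with
``theta = 1``; everything else with ``l = 0, theta = 0``.  At every
synchronous step a labeled neighbour ``q`` attacks ``p`` when

    g(C_p, C_q) * theta_q > theta_p,

in which case ``p`` takes ``q``'s label with strength ``g * theta_q``.  Two
energy (similarity) functions are provided:

* traditional:  g = 1 - |C_p - C_q| / max||C||,   clamped to [0, 1];
* improved:     g = exp(-(I_p - I_q)^2 / (2 sigma^2)) / dist(p, q),

the improved one also penalising the pixel distance (1 for axial Moore
neighbours, sqrt(2) for diagonal), which sharpens the competition at weak
edges.  An optional boundary-smoothing extension counts each cell's
"enemies" (the maximum, over rival labels, of differently-labeled
neighbours): a cell with enemies >= T1 may not attack, and a cell with
enemies >= T2 is forcibly occupied by its weakest enemy neighbour even if
that enemy is weaker.  Iteration stops when no label changes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from liverseg.image_io import SeedMap

__all__ = [
    "MOORE_OFFSETS",
    "VON_NEUMANN_OFFSETS",
    "CellState",
    "GrowCutConfig",
    "GrowCutResult",
    "init_state",
    "energy_traditional",
    "energy_improved",
    "enemies_count",
    "evolve_step",
    "run",
    "estimate_sigma2",
]

# Fixed tie-break order: N, NE, E, SE, S, SW, W, NW (row, col offsets).
MOORE_OFFSETS: tuple[tuple[int, int], ...] = (
    (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1),
)
VON_NEUMANN_OFFSETS: tuple[tuple[int, int], ...] = ((-1, 0), (0, 1), (1, 0), (0, -1))

SIGMA2_FLOOR = 1e-6


@dataclass(frozen=True)
class CellState:
    """Per-pixel (label, strength, feature) grids of the automaton."""

    label: np.ndarray     # int labels, 0 = unlabeled
    strength: np.ndarray  # theta in [0, 1]
    feature: np.ndarray   # C (gray value)

    def __post_init__(self) -> None:
        if not (self.label.shape == self.strength.shape == self.feature.shape):
            raise ValueError("label, strength and feature grids must share a shape")


@dataclass(frozen=True)
class GrowCutConfig:
    energy: str = "improved"            # "traditional" | "improved"
    neighborhood: str = "moore"         # "moore" | "von_neumann"
    sigma2: "float | str" = "auto"      # improved-energy scale, or "auto"
    t1: int = 6                         # smoothing: attack prohibition threshold
    t2: int = 7                         # smoothing: forced-occupation threshold
    smoothing: bool = False
    max_iter: int = 500
    feature_norm: "float | str" = 255.0  # traditional-energy max||C||, or "auto"

    def offsets(self) -> tuple[tuple[int, int], ...]:
        if self.neighborhood == "moore":
            return MOORE_OFFSETS
        if self.neighborhood == "von_neumann":
            return VON_NEUMANN_OFFSETS
        raise ValueError(f"unknown neighborhood {self.neighborhood!r}")

    def validate(self) -> None:
        if self.energy not in ("traditional", "improved"):
            raise ValueError(f"unknown energy {self.energy!r}")
        self.offsets()
        if self.smoothing:
            n = len(self.offsets())
            if not (0 < self.t1 <= self.t2 <= n):
                raise ValueError(f"need 0 < T1 <= T2 <= {n} when smoothing is on")


@dataclass(frozen=True)
class GrowCutResult:
    label: np.ndarray
    strength: np.ndarray
    iterations: int
    trace: tuple[int, ...]   # changed-cell count per iteration
    converged: bool
    cells_visited: int       # iterations * grid size (work measure)

    @property
    def foreground(self) -> np.ndarray:
        return (self.label == 1).astype(np.uint8)


def init_state(image: np.ndarray, seeds: SeedMap) -> CellState:
    """Seed labels at strength 1; all other cells unlabeled at strength 0."""
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError("image must be a non-empty 2-D array")
    seeds.check_bounds(arr.shape)
    if len(seeds.distinct_labels) < 2:
        raise ValueError("seeds must carry at least two distinct labels")
    label = np.zeros(arr.shape, dtype=np.int64)
    strength = np.zeros(arr.shape, dtype=np.float64)
    label[seeds.rows, seeds.cols] = seeds.labels
    strength[seeds.rows, seeds.cols] = 1.0
    return CellState(label=label, strength=strength, feature=arr)


def energy_traditional(cp, cq, feature_norm: float = 255.0):
    """g = 1 - |C_p - C_q| / max||C||, clamped to [0, 1]."""
    if feature_norm <= 0:
        raise ValueError("feature_norm must be positive")
    return np.clip(1.0 - np.abs(np.subtract(cp, cq)) / feature_norm, 0.0, 1.0)


def energy_improved(ip, iq, sigma2: float, dist: float):
    """g = exp(-(I_p - I_q)^2 / (2 sigma^2)) / dist(p, q)."""
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    if dist <= 0:
        raise ValueError("dist must be positive")
    d = np.subtract(ip, iq)
    return np.exp(-(d * d) / (2.0 * sigma2)) / dist


def _pair_energy(cp, cq, config: GrowCutConfig, dist: float):
    if config.energy == "traditional":
        return energy_traditional(cp, cq, config.feature_norm)
    return energy_improved(cp, cq, config.sigma2, dist)


def _pq_slices(shape, dr: int, dc: int):
    """Aligned slices so that a[qs] holds the (dr, dc)-neighbour of a[ps]."""
    h, w = shape
    ps = (slice(max(0, -dr), h - max(0, dr)), slice(max(0, -dc), w - max(0, dc)))
    qs = (slice(max(0, dr), h - max(0, -dr)), slice(max(0, dc), w - max(0, -dc)))
    return ps, qs


def _enemy_counts(label: np.ndarray, offsets) -> np.ndarray:
    """Per-cell max over rival labels of differently-labeled neighbours."""
    enemies = np.zeros(label.shape, dtype=np.int64)
    for val in np.unique(label):
        if val == 0:
            continue
        cnt = np.zeros(label.shape, dtype=np.int64)
        member = label == val
        for dr, dc in offsets:
            ps, qs = _pq_slices(label.shape, dr, dc)
            cnt[ps] += member[qs]
        cnt[member] = 0  # a cell's own label is not an enemy
        np.maximum(enemies, cnt, out=enemies)
    return enemies


def enemies_count(state: CellState, p: tuple[int, int], neighborhood: str = "moore") -> int:
    """Enemy count of a single pixel (unlabeled neighbours do not count)."""
    offsets = GrowCutConfig(neighborhood=neighborhood).offsets()
    h, w = state.label.shape
    r, c = p
    if not (0 <= r < h and 0 <= c < w):
        raise ValueError(f"pixel {p} outside a {h}x{w} grid")
    own = state.label[r, c]
    counts: dict[int, int] = {}
    for dr, dc in offsets:
        rr, cc = r + dr, c + dc
        if 0 <= rr < h and 0 <= cc < w:
            lq = int(state.label[rr, cc])
            if lq != 0 and lq != own:
                counts[lq] = counts.get(lq, 0) + 1
    return max(counts.values(), default=0)


def evolve_step(state: CellState, config: GrowCutConfig) -> tuple[CellState, int]:
    """One synchronous automaton step; returns the new state and the number
    of cells whose label changed.

    All reads come from the step-t state.  Per pixel the winning attacker is
    the neighbour maximising ``g * theta_q`` among those strictly exceeding
    ``theta_p``; ties break to the first neighbour in the fixed offset order.
    With smoothing on, cells with enemies >= T1 may not attack, and after the
    attack phase any cell with enemies >= T2 is captured by its weakest enemy
    neighbour (minimum theta, ties again by offset order).
    """
    config.validate()
    if not isinstance(config.sigma2, (int, float)) and config.energy == "improved":
        raise ValueError("sigma2 must be numeric at evolve time (resolve 'auto' first)")
    lab, th, feat = state.label, state.strength, state.feature
    shape = lab.shape
    offsets = config.offsets()
    new_lab = lab.copy()
    new_th = th.copy()
    best = th.copy()  # attack strength to beat, starts at theta_p
    enemies = _enemy_counts(lab, offsets) if config.smoothing else None
    if config.smoothing:
        may_attack = (lab != 0) & (enemies < config.t1)
    else:
        may_attack = lab != 0
    for dr, dc in offsets:
        dist = float(np.sqrt(dr * dr + dc * dc))
        ps, qs = _pq_slices(shape, dr, dc)
        g = _pair_energy(feat[ps], feat[qs], config, dist)
        atk = g * th[qs]
        cond = may_attack[qs] & (atk > best[ps])
        if cond.any():
            best[ps][cond] = atk[cond]
            new_lab[ps][cond] = lab[qs][cond]
            new_th[ps][cond] = atk[cond]
    if config.smoothing:
        forced = enemies >= config.t2
        if forced.any():
            weakest = np.full(shape, np.inf)
            occ_lab = np.zeros(shape, dtype=lab.dtype)
            occ_th = np.zeros(shape, dtype=np.float64)
            for dr, dc in offsets:
                dist = float(np.sqrt(dr * dr + dc * dc))
                ps, qs = _pq_slices(shape, dr, dc)
                enemy = (lab[qs] != 0) & (lab[qs] != lab[ps])
                cond = forced[ps] & enemy & (th[qs] < weakest[ps])
                if cond.any():
                    g = _pair_energy(feat[ps], feat[qs], config, dist)
                    weakest[ps][cond] = th[qs][cond]
                    occ_lab[ps][cond] = lab[qs][cond]
                    occ_th[ps][cond] = (g * th[qs])[cond]
            take = forced & np.isfinite(weakest)
            new_lab[take] = occ_lab[take]
            new_th[take] = occ_th[take]
    changed = int(np.count_nonzero(new_lab != lab))
    return CellState(label=new_lab, strength=new_th, feature=feat), changed


def run(
    image: np.ndarray,
    seeds: SeedMap,
    config: "GrowCutConfig | None" = None,
) -> GrowCutResult:
    """Iterate :func:`evolve_step` until no label changes or ``max_iter``."""
    config = config or GrowCutConfig()
    config = resolve_config(image, config)
    state = init_state(image, seeds)
    trace: list[int] = []
    converged = False
    iterations = 0
    for iterations in range(1, config.max_iter + 1):
        new_state, changed = evolve_step(state, config)
        trace.append(changed)
        # a quiet step is not enough: strengths may still be propagating and
        # can enable captures later, so require a full fixed point
        if changed == 0 and np.array_equal(new_state.strength, state.strength):
            state = new_state
            converged = True
            break
        state = new_state
    if config.max_iter == 0:
        iterations = 0
    if not converged:
        warnings.warn(
            f"GrowCut did not converge within {config.max_iter} iterations",
            RuntimeWarning,
            stacklevel=2,
        )
    return GrowCutResult(
        label=state.label,
        strength=state.strength,
        iterations=iterations,
        trace=tuple(trace),
        converged=converged,
        cells_visited=iterations * int(np.prod(state.label.shape)),
    )


def resolve_config(image: np.ndarray, config: GrowCutConfig) -> GrowCutConfig:
    """Resolve "auto" parameters against the image the automaton will see."""
    config.validate()
    arr = np.asarray(image, dtype=np.float64)
    updates: dict = {}
    if config.energy == "improved" and config.sigma2 == "auto":
        updates["sigma2"] = estimate_sigma2(arr)
    if config.energy == "traditional" and config.feature_norm == "auto":
        span = float(arr.max() - arr.min())
        updates["feature_norm"] = span if span > 0 else 255.0
    return replace(config, **updates) if updates else config


def estimate_sigma2(
    image: np.ndarray,
    roi_mask: "np.ndarray | None" = None,
    floor: float = SIGMA2_FLOOR,
) -> float:
    """Variance of axial neighbour intensity differences over the ROI.

    Shift-invariant; a constant image returns ``floor`` with a warning.
    """
    arr = np.asarray(image, dtype=np.float64)
    dh = arr[:, 1:] - arr[:, :-1]
    dv = arr[1:, :] - arr[:-1, :]
    if roi_mask is not None:
        m = np.asarray(roi_mask).astype(bool)
        dh = dh[m[:, 1:] & m[:, :-1]]
        dv = dv[m[1:, :] & m[:-1, :]]
    diffs = np.concatenate([np.ravel(dh), np.ravel(dv)])
    if diffs.size == 0:
        warnings.warn("ROI too small to estimate sigma2; using floor", RuntimeWarning)
        return floor
    var = float(np.var(diffs))
    if var < floor:
        warnings.warn("image is (near-)constant; sigma2 floored", RuntimeWarning)
        return floor
    return var
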