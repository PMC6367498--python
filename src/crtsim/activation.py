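"""Synthetic ventricular activation maps for two-site pacing.

The mapped canine preparation is emulated on an abstract geometry: the 52
LV-free-wall, 50 RV-free-wall and 10 septal segments (7 on the RV side of
the septum, 3 on the LV side) are nodes of per-wall 2-D lattices joined at
the apex/septal insertions, and the quantity carried per segment is its
geodesic path length to each of the two pacing sites (RV apex; LV basal
posterolateral epicardium).  Spatial location beyond these two distances
is never needed downstream — the wall mechanics is location-free — so the
lattice exists only to produce a consistent, triangle-inequality-obeying
pair of distance fields with the experiment's left/right asymmetry.

Activation under a pacing-delay pair follows the earliest-arrival rule
with wavefront fusion: ``t(s) = min_i (pace_i + dist_i(s)/v)`` over the
*captured* sources; a site loses capture when the contralateral wavefront
reaches it before its own stimulus fires.  Optional per-segment Gaussian
jitter emulates measurement noise; a virtual cohort of dogs perturbs the
per-wall geometry scales, and the per-wall sorted elementwise median
across dogs gives the generic activation pattern imposed on the model.

Sign convention: VEU = mean LVFW − mean RVFW activation time; positive
means the LV free wall is activated late (as in RV-only pacing / LBBB).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

__all__ = [
    "WALL_LVFW", "WALL_RVFW", "WALL_SEPT_RV", "WALL_SEPT_LV",
    "N_LVFW", "N_RVFW", "N_SEPT_RV", "N_SEPT_LV", "N_SEGMENTS",
    "GeneratorParams", "SegmentGeometry", "Geometry", "ActivationMap",
    "DyssynchronyIndices", "build_geometry", "simulate_activation",
    "virtual_cohort", "generic_pattern", "generic_maps",
    "dyssynchrony_indices", "write_maps", "read_maps", "read_map",
]

WALL_LVFW = "LVFW"
WALL_RVFW = "RVFW"
WALL_SEPT_RV = "SEPTUM_RV_SIDE"
WALL_SEPT_LV = "SEPTUM_LV_SIDE"

N_LVFW = 52
N_RVFW = 50
N_SEPT_RV = 7
N_SEPT_LV = 3
N_SEGMENTS = N_LVFW + N_RVFW + N_SEPT_RV + N_SEPT_LV

# lattice shapes: (columns, rows); column 0 faces the septum
_LV_SHAPE = (4, 13)
_RV_SHAPE = (5, 10)


@dataclass
class GeneratorParams:
    """Tunable parameters of the synthetic activation generator.

    v_cond        : myocardial conduction velocity (mm/ms)
    jitter_sd     : per-segment Gaussian noise SD (ms), clipped at 3 SD
    n_dogs        : virtual cohort size
    seed          : root RNG seed (per-dog / per-setting substreams are
                    spawned from it by numpy SeedSequence in fixed order)
    wall_scale    : per-wall multiplier on lattice edge lengths; the LVFW
                    default > 1 makes the LV free wall effectively larger/
                    slower, which produces the experiment's asymmetric VEU
                    magnitudes
    dog_geom_sd   : SD of the per-dog perturbation of the wall scales
    remaining fields: lattice spacings and junction edge lengths (mm)
    """

    v_cond: float = 0.8
    jitter_sd: float = 3.0
    n_dogs: int = 6
    seed: int = 20190017
    wall_scale: dict = field(default_factory=lambda: {
        "LVFW": 1.5, "RVFW": 1.0, "SEPT": 1.0})
    dog_geom_sd: float = 0.05
    sp_lv_x: float = 5.0
    sp_lv_y: float = 3.2
    sp_rv_x: float = 3.2
    sp_rv_y: float = 2.6
    sp_sept_rv: float = 3.0
    sp_sept_lv: float = 14.0
    w_insert_rv: float = 3.0
    w_insert_lv: float = 5.0
    w_transmural: float = 6.0
    n_insert_rows: int = 2      # apical rows carrying septal insertions
    w_groove: float | None = None  # free-wall junction edges, None = off
    cross_slow: float = 1.3     # slowing of a wavefront that has crossed
    #   into the contralateral free wall (no Purkinje pre-excitation,
    #   predominantly transmural cell-to-cell spread)

    def __post_init__(self) -> None:
        if self.v_cond <= 0:
            raise ValueError("v_cond must be positive")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be non-negative")
        if self.n_dogs < 1:
            raise ValueError("n_dogs must be >= 1")


@dataclass
class SegmentGeometry:
    """One segment's wall label and path lengths (mm) to the pacing
    sites."""

    segment_id: int
    wall: str
    dist_rv_site: float
    dist_lv_site: float


@dataclass
class Geometry:
    """The 112-segment layout: wall labels and per-segment geodesic path
    lengths to both pacing sites."""

    wall: np.ndarray          # str array, length 112
    dist_rv_site: np.ndarray  # mm
    dist_lv_site: np.ndarray  # mm
    rv_site_segment: int
    lv_site_segment: int

    @property
    def segment_id(self) -> np.ndarray:
        return np.arange(N_SEGMENTS)

    @property
    def inter_site_distance(self) -> float:
        """Geodesic path length between the two pacing sites (mm), as
        seen by the RV-site wavefront."""
        return float(self.dist_rv_site[self.lv_site_segment])

    @property
    def rv_to_lv_site(self) -> float:
        """RV-site wavefront's path length to the LV pacing site (mm)."""
        return float(self.dist_rv_site[self.lv_site_segment])

    @property
    def lv_to_rv_site(self) -> float:
        """LV-site wavefront's path length to the RV pacing site (mm)."""
        return float(self.dist_lv_site[self.rv_site_segment])

    def segments(self) -> list[SegmentGeometry]:
        return [SegmentGeometry(i, self.wall[i],
                                float(self.dist_rv_site[i]),
                                float(self.dist_lv_site[i]))
                for i in range(N_SEGMENTS)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "segment_id": self.segment_id, "wall": self.wall,
            "dist_rv_site": self.dist_rv_site,
            "dist_lv_site": self.dist_lv_site})


def _grid_edges(n0, cols, rows, sx, sy, scale):
    """8-neighbour lattice edges for a cols x rows grid whose node ids are
    n0 + col*rows + row."""
    edges = []
    diag = np.hypot(sx, sy)
    for c in range(cols):
        for r in range(rows):
            i = n0 + c * rows + r
            if r + 1 < rows:
                edges.append((i, i + 1, sy * scale))
            if c + 1 < cols:
                edges.append((i, i + rows, sx * scale))
                if r + 1 < rows:
                    edges.append((i, i + rows + 1, diag * scale))
                if r - 1 >= 0:
                    edges.append((i, i + rows - 1, diag * scale))
    return edges


def build_geometry(params: GeneratorParams,
                   wall_scale: dict | None = None) -> Geometry:
    """Build the 112-segment layout and precompute geodesic distances from
    both pacing sites.  Deterministic for given parameters.

    Node order: LVFW (column-major, column 0 septal, row 0 apical), then
    septal RV side, septal LV side, then RVFW.  The RV apex pacing site is
    the apical-septal RVFW segment; the LV site is the basal far-column
    (posterolateral) LVFW segment.
    """
    sc = dict(params.wall_scale)
    if wall_scale:
        sc.update(wall_scale)
    lv0 = 0
    srv0 = N_LVFW
    slv0 = N_LVFW + N_SEPT_RV
    rv0 = N_LVFW + N_SEPT_RV + N_SEPT_LV

    lv_internal = _grid_edges(lv0, *_LV_SHAPE, params.sp_lv_x,
                              params.sp_lv_y, sc["LVFW"])
    rv_internal = _grid_edges(rv0, *_RV_SHAPE, params.sp_rv_x,
                              params.sp_rv_y, sc["RVFW"])
    edges = []
    # septal chains (apex = index 0)
    for k in range(N_SEPT_RV - 1):
        edges.append((srv0 + k, srv0 + k + 1, params.sp_sept_rv * sc["SEPT"]))
    for k in range(N_SEPT_LV - 1):
        edges.append((slv0 + k, slv0 + k + 1, params.sp_sept_lv * sc["SEPT"]))
    # transmural septum: LV-side node to nearest RV-side nodes by height
    h_srv = np.arange(N_SEPT_RV) * params.sp_sept_rv
    h_slv = np.arange(N_SEPT_LV) * params.sp_sept_lv
    for k in range(N_SEPT_LV):
        j = int(np.argmin(np.abs(h_srv - h_slv[k])))
        edges.append((slv0 + k, srv0 + j, params.w_transmural * sc["SEPT"]))
    # insertions: apical rows of the septal free-wall columns attach to the
    # septal chain at matching heights
    for r in range(params.n_insert_rows):
        j = int(np.argmin(np.abs(h_srv - r * params.sp_rv_y)))
        edges.append((rv0 + r, srv0 + j, params.w_insert_rv * sc["SEPT"]))
    # the LV septal surface is reachable over its whole height, so every
    # LV-side septal node attaches to the nearest LVFW septal-column row
    lv_rows_h = np.arange(_LV_SHAPE[1]) * params.sp_lv_y
    for k in range(N_SEPT_LV):
        r = int(np.argmin(np.abs(lv_rows_h - h_slv[k])))
        edges.append((lv0 + r, slv0 + k, params.w_insert_lv * sc["SEPT"]))
    # optional anterior/posterior groove between the free walls' far columns
    if params.w_groove is not None:
        lv_cols, lv_rows = _LV_SHAPE
        rv_cols, rv_rows = _RV_SHAPE
        for r in range(min(lv_rows, rv_rows)):
            edges.append((lv0 + (lv_cols - 1) * lv_rows + r,
                          rv0 + (rv_cols - 1) * rv_rows + r,
                          params.w_groove))

    def _dist(edge_list, source):
        rows = [e[0] for e in edge_list] + [e[1] for e in edge_list]
        cols = [e[1] for e in edge_list] + [e[0] for e in edge_list]
        w = [e[2] for e in edge_list] * 2
        graph = coo_matrix((w, (rows, cols)),
                           shape=(N_SEGMENTS, N_SEGMENTS)).tocsr()
        return dijkstra(graph, directed=False, indices=source)

    rv_site = rv0  # RVFW column 0, row 0: apical, at the septal edge
    lv_cols, lv_rows = _LV_SHAPE
    lv_site = lv0 + (lv_cols - 1) * lv_rows + (lv_rows - 1)  # basal far corner
    # each source sees native conduction on its own side but slowed spread
    # through the contralateral free wall (cross_slow)
    f = params.cross_slow
    scale_e = lambda es, g: [(a, b, w * g) for a, b, w in es]  # noqa: E731
    d_rv = _dist(edges + rv_internal + scale_e(lv_internal, f), rv_site)
    d_lv = _dist(edges + lv_internal + scale_e(rv_internal, f), lv_site)
    wall = np.array([WALL_LVFW] * N_LVFW + [WALL_SEPT_RV] * N_SEPT_RV +
                    [WALL_SEPT_LV] * N_SEPT_LV + [WALL_RVFW] * N_RVFW)
    return Geometry(wall=wall, dist_rv_site=d_rv, dist_lv_site=d_lv,
                    rv_site_segment=rv_site, lv_site_segment=lv_site)


@dataclass
class ActivationMap:
    """Per-segment onset-of-activation times for one pacing setting.

    a_lv / a_rv are programmed atrio-ventricular delays in ms, or None for
    a ventricle that is not paced; t_act is ms after the atrial pace.
    """

    a_lv: float | None
    a_rv: float | None
    t_act: np.ndarray
    wall: np.ndarray
    captured_lv: bool
    captured_rv: bool

    @property
    def segment_id(self) -> np.ndarray:
        return np.arange(len(self.t_act))

    def setting(self) -> tuple:
        return (self.a_lv, self.a_rv)


@dataclass
class DyssynchronyIndices:
    """Electrical dyssynchrony summary of one map (ms).

    lv_tat covers the whole LV (free wall plus both septal electrode
    groups); rv_tat the RV free wall only; veu = mean LVFW − mean RVFW
    (positive = LV free wall late)."""

    lv_tat: float
    rv_tat: float
    veu: float


def simulate_activation(a_lv, a_rv, geometry: Geometry,
                        params: GeneratorParams,
                        rng: np.random.Generator | None = None
                        ) -> ActivationMap:
    """Earliest-arrival activation map for one pacing-delay pair.

    A source is captured iff its stimulus fires strictly before the
    contralateral wavefront arrives at its site; the map is the pointwise
    minimum of the captured sources' arrival fields plus optional clipped
    Gaussian jitter, floored so no segment precedes the earliest captured
    stimulus.
    """
    if a_lv is None and a_rv is None:
        raise ValueError("no ventricular pacing source: both delays None")
    v = params.v_cond
    cap_lv = a_lv is not None and (
        a_rv is None or a_lv < a_rv + geometry.rv_to_lv_site / v)
    cap_rv = a_rv is not None and (
        a_lv is None or a_rv < a_lv + geometry.lv_to_rv_site / v)
    t = np.full(N_SEGMENTS, np.inf)
    if cap_lv:
        t = np.minimum(t, a_lv + geometry.dist_lv_site / v)
    if cap_rv:
        t = np.minimum(t, a_rv + geometry.dist_rv_site / v)
    if params.jitter_sd > 0:
        if rng is None:
            rng = np.random.default_rng(params.seed)
        j = rng.normal(0.0, params.jitter_sd, N_SEGMENTS)
        j = np.clip(j, -3.0 * params.jitter_sd, 3.0 * params.jitter_sd)
        floor = min(p for p, c in ((a_lv, cap_lv), (a_rv, cap_rv)) if c)
        t = np.maximum(t + j, floor)
    return ActivationMap(a_lv=a_lv, a_rv=a_rv, t_act=t,
                         wall=geometry.wall.copy(),
                         captured_lv=cap_lv, captured_rv=cap_rv)


def virtual_cohort(settings, params: GeneratorParams,
                   n_dogs: int | None = None, seed: int | None = None
                   ) -> dict:
    """Simulate the pacing settings in a cohort of virtual dogs.

    Each dog perturbs the per-wall geometry scales and draws its own
    jitter; substreams are spawned from the root seed in fixed order
    (dog-major, then setting), so results are reproducible and independent
    of which settings are requested together.

    Returns {setting: [ActivationMap per dog]}.
    """
    n_dogs = params.n_dogs if n_dogs is None else n_dogs
    if n_dogs < 1:
        raise ValueError("n_dogs must be >= 1")
    seed = params.seed if seed is None else seed
    root = np.random.SeedSequence(seed)
    dog_seeds = root.spawn(n_dogs)
    out = {tuple(s): [] for s in settings}
    for d in range(n_dogs):
        geom_ss, jitter_ss = dog_seeds[d].spawn(2)
        g_rng = np.random.default_rng(geom_ss)
        scale = {}
        for wname in ("LVFW", "RVFW", "SEPT"):
            z = np.clip(g_rng.normal(), -3.0, 3.0)
            scale[wname] = params.wall_scale[wname] * (
                1.0 + params.dog_geom_sd * z)
        geom = build_geometry(params, wall_scale=scale)
        setting_seeds = jitter_ss.spawn(len(out))
        for (a_lv, a_rv), ss in zip(out, setting_seeds):
            rng = np.random.default_rng(ss)
            out[(a_lv, a_rv)].append(
                simulate_activation(a_lv, a_rv, geom, params, rng=rng))
    return out


# wall groups whose activation times are pooled and sorted together when
# forming the generic pattern: the septum is one mechanical wall
_SORT_GROUPS = (
    (WALL_LVFW,), (WALL_SEPT_RV, WALL_SEPT_LV), (WALL_RVFW,))


def generic_pattern(maps) -> ActivationMap:
    """Generic activation pattern: per mechanical wall, sort each map's
    times ascending and take the elementwise median across maps.

    The order of patches within a wall is immaterial downstream (common
    wall tension), which is what licenses the sorting.  Capture flags are
    decided by majority.
    """
    maps = list(maps)
    if not maps:
        raise ValueError("generic_pattern needs at least one map")
    first = maps[0]
    for m in maps[1:]:
        if m.setting() != first.setting():
            raise ValueError("maps mix pacing settings "
                             f"{m.setting()} vs {first.setting()}")
        if len(m.t_act) != len(first.t_act) or np.any(m.wall != first.wall):
            raise ValueError("maps do not share one segment layout")
    t_out = np.empty_like(first.t_act)
    for group in _SORT_GROUPS:
        idx = np.flatnonzero(np.isin(first.wall, group))
        stacked = np.sort(
            np.stack([m.t_act[idx] for m in maps]), axis=1)
        t_out[idx] = np.median(stacked, axis=0)
    n = len(maps)
    return ActivationMap(
        a_lv=first.a_lv, a_rv=first.a_rv, t_act=t_out,
        wall=first.wall.copy(),
        captured_lv=sum(m.captured_lv for m in maps) * 2 > n,
        captured_rv=sum(m.captured_rv for m in maps) * 2 > n)


def generic_maps(settings, params: GeneratorParams) -> dict:
    """Generic activation map per setting from a fresh virtual cohort."""
    cohort = virtual_cohort(settings, params)
    return {s: generic_pattern(ms) for s, ms in cohort.items()}


def dyssynchrony_indices(amap: ActivationMap) -> DyssynchronyIndices:
    """TAT and VEU indices; LV TAT spans the free wall plus both septal
    groups, RV TAT the RV free wall only."""
    lv_sel = np.isin(amap.wall, (WALL_LVFW, WALL_SEPT_RV, WALL_SEPT_LV))
    rv_sel = amap.wall == WALL_RVFW
    lvfw = amap.wall == WALL_LVFW
    t = amap.t_act
    return DyssynchronyIndices(
        lv_tat=float(t[lv_sel].max() - t[lv_sel].min()),
        rv_tat=float(t[rv_sel].max() - t[rv_sel].min()),
        veu=float(t[lvfw].mean() - t[rv_sel].mean()))


# ---------------------------------------------------------------------------
# CSV I/O

_COLUMNS = ["segment_id", "wall", "a_lv", "a_rv", "t_act_ms",
            "captured_lv", "captured_rv"]


def _delay_str(a) -> str:
    return "none" if a is None else f"{float(a):g}"


def _delay_val(s):
    return None if str(s) == "none" else float(s)


def write_maps(path, maps) -> None:
    """Write one or more activation maps to CSV (one row per segment, maps
    distinguished by their delay columns)."""
    if isinstance(maps, ActivationMap):
        maps = [maps]
    frames = []
    for m in maps:
        frames.append(pd.DataFrame({
            "segment_id": m.segment_id, "wall": m.wall,
            "a_lv": _delay_str(m.a_lv), "a_rv": _delay_str(m.a_rv),
            "t_act_ms": np.round(m.t_act, 6),
            "captured_lv": m.captured_lv, "captured_rv": m.captured_rv}))
    pd.concat(frames).to_csv(path, index=False)


def read_maps(path) -> list:
    """Read activation maps back from CSV; inverse of write_maps."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - re-raise with file context
        raise ValueError(f"cannot parse activation-map CSV {path}: {exc}")
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(
            f"activation-map CSV {path} lacks columns {missing}")
    out = []
    for (a_lv_s, a_rv_s), grp in df.groupby(["a_lv", "a_rv"], sort=False):
        if len(grp) != N_SEGMENTS:
            raise ValueError(
                f"activation-map CSV {path}: setting ({a_lv_s}, {a_rv_s}) "
                f"has {len(grp)} segments, expected {N_SEGMENTS}")
        grp = grp.sort_values("segment_id")
        if not np.array_equal(grp["segment_id"].to_numpy(),
                              np.arange(N_SEGMENTS)):
            raise ValueError(
                f"activation-map CSV {path}: segment ids must be a "
                f"permutation of 0..{N_SEGMENTS - 1}")
        out.append(ActivationMap(
            a_lv=_delay_val(a_lv_s), a_rv=_delay_val(a_rv_s),
            t_act=grp["t_act_ms"].to_numpy(float),
            wall=grp["wall"].to_numpy(),
            captured_lv=bool(grp["captured_lv"].iloc[0]),
            captured_rv=bool(grp["captured_rv"].iloc[0])))
    return out


def read_map(path) -> ActivationMap:
    maps = read_maps(path)
    if len(maps) != 1:
        raise ValueError(f"{path} holds {len(maps)} maps, expected one")
    return maps[0]
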