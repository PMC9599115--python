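"""Mechanistic spine/dendrite calcium dynamics.

Calcium enters through the NMDA receptor (a fixed fraction of its current)
and the lumped voltage-gated calcium conductance, binds to mobile buffers
(calbindin, calmodulin N- and C-lobes) and an endogenous immobile buffer by
mass action, diffuses in one dimension — axially through cylindrical slabs
of the spine head and neck into the submembrane shell of the dendritic
shaft, radially between concentric shells within the shaft — and is extruded
by Michaelis-Menten pumps: plasma-membrane calcium ATPase (PMCA) on every
membrane element and sodium-calcium exchanger (NCX) restricted to spines.
A constant leak influx equal to the resting pump flux makes the configured
baseline a fixed point.

Buffer and pump constants are not direct measurements; they are standard
values from the calcium-imaging-constrained modelling literature, with pump
capacity calibrated so one synaptic event yields a spine transient of order
0.1-1 µM.  Units: µM, ms, µm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .morphology import (
    SPINE_HEAD_DIAM,
    SPINE_HEAD_LEN,
    SPINE_NECK_DIAM,
    SPINE_NECK_LEN,
    Morphology,
    SpineSet,
)

__all__ = [
    "BufferSpec",
    "PumpSpec",
    "CalciumParams",
    "CalciumModel",
    "CalciumState",
    "default_buffers",
    "resting_state",
    "step_calcium",
]

# charge -> concentration: dCa (µM/ms) = CURRENT_TO_FLUX * I (nA) / volume (µm^3)
# (1 nA = 1e-12 C/ms; /2F mol/C; /1e-15 L per µm^3; x1e6 µM per M)
CURRENT_TO_FLUX = 1e9 / (2.0 * 96485.332)  # = 5182.1 µM µm^3 / (nA ms)

N_SHELLS = 3          # radial shells per dendritic segment
SUBMEMBRANE_UM = 0.1  # thickness of the outermost (submembrane) shell
N_HEAD_SLABS = 2
N_NECK_SLABS = 2


@dataclass(frozen=True)
class BufferSpec:
    """One calcium-binding species (mass-action 1:1 binding)."""

    name: str
    total_um: float       # µM
    k_on: float           # 1/(µM ms)
    k_off: float          # 1/ms
    d_coef: float         # µm^2/ms, 0 for the immobile buffer

    def __post_init__(self):
        if self.total_um < 0 or self.k_on <= 0 or self.k_off <= 0 or self.d_coef < 0:
            raise ValueError("invalid buffer parameters")

    @property
    def kd(self) -> float:
        return self.k_off / self.k_on


def default_buffers() -> tuple[BufferSpec, ...]:
    """Calbindin, calmodulin N/C lobes, and an endogenous immobile buffer.

    Kinetics are the values commonly used in striatal/hippocampal spine
    models: calbindin (high-affinity medium site, Kd 0.7 µM, D 0.027
    µm^2/ms), a fast low-affinity calmodulin N-lobe and a slower
    high-affinity C-lobe (D 0.066), and a fast immobile buffer with binding
    ratio ~20.
    """
    return (
        BufferSpec("calbindin", 80.0, 0.028, 0.0196, 0.027),
        BufferSpec("calmodulin_n", 15.0, 0.2, 3.8, 0.066),
        BufferSpec("calmodulin_c", 15.0, 0.05, 0.013, 0.066),
        BufferSpec("immobile", 300.0, 0.02, 0.3, 0.0),
    )


@dataclass(frozen=True)
class PumpSpec:
    """Michaelis-Menten surface pump: flux = vmax*area*[Ca]/([Ca]+Km)."""

    vmax: float  # µM µm / ms (surface density x turnover)
    km: float    # µM

    def __post_init__(self):
        if self.vmax < 0 or self.km <= 0:
            raise ValueError("need vmax >= 0 and km > 0")


@dataclass(frozen=True)
class CalciumParams:
    buffers: tuple = field(default_factory=default_buffers)
    pmca: PumpSpec = PumpSpec(vmax=0.2, km=0.3)
    ncx: PumpSpec = PumpSpec(vmax=0.5, km=1.0)
    d_ca: float = 0.2          # µm^2/ms free calcium diffusion
    baseline_um: float = 0.05  # resting free calcium (50 nM)


@dataclass
class CalciumState:
    """Free calcium plus free/bound concentration of each buffer, per element."""

    ca: np.ndarray          # (n_elem,)
    buf_free: np.ndarray    # (n_buf, n_elem)
    buf_bound: np.ndarray   # (n_buf, n_elem)

    def copy(self) -> "CalciumState":
        return CalciumState(self.ca.copy(), self.buf_free.copy(), self.buf_bound.copy())

    def total_calcium(self, volumes: np.ndarray) -> float:
        """Volume-weighted total calcium (free + bound, µM µm^3)."""
        return float(
            np.sum(self.ca * volumes) + np.sum(self.buf_bound * volumes[None, :])
        )


class CalciumModel:
    """Geometry + parameters of the coupled spine/dendrite calcium system.

    Builds the element stack for every dendritic segment that carries a
    modelled spine (slabs of each spine head and neck, radial shells of the
    shaft) and precomputes diffusion couplings, membrane areas and pump
    tables.  ``spine_head_elems[k]`` are the head-slab element indices of
    spine k (their volume-weighted mean is the spine calcium of the
    plasticity rule).
    """

    def __init__(
        self,
        morph: Morphology,
        spines: SpineSet,
        spine_index=None,
        params: CalciumParams | None = None,
        neck_length: float = SPINE_NECK_LEN,
        head_length: float = SPINE_HEAD_LEN,
    ):
        self.params = params or CalciumParams()
        self.neck_length = neck_length
        self.head_length = head_length
        if spine_index is None:
            spine_index = np.arange(spines.n_spines)
        self.spine_index = np.asarray(spine_index, dtype=int)
        self.morph = morph
        self.spines = spines

        segs = np.unique(spines.segment[self.spine_index])
        self.segments = segs  # modelled dendritic segments
        seg_elem0 = {}        # segment -> index of its outermost (submembrane) shell

        volumes: list[float] = []
        memb_area: list[float] = []
        is_spine: list[bool] = []
        pairs: list[tuple[int, int, float]] = []  # (i, j, area/dx)

        for s in segs:
            r = morph.diameter[s] / 2.0
            L = morph.length[s]
            sub = min(SUBMEMBRANE_UM, r / 2.0)
            # shell boundaries from membrane inward: outer shell `sub` thick,
            # remaining radius split evenly
            inner = np.linspace(r - sub, 0.0, N_SHELLS)
            bounds = np.concatenate(([r], inner))
            base = len(volumes)
            seg_elem0[int(s)] = base
            mids = 0.5 * (bounds[:-1] + bounds[1:])
            for k in range(N_SHELLS):
                ro, ri = bounds[k], bounds[k + 1]
                volumes.append(np.pi * (ro**2 - ri**2) * L)
                memb_area.append(np.pi * morph.diameter[s] * L if k == 0 else 0.0)
                is_spine.append(False)
            for k in range(N_SHELLS - 1):
                a = 2.0 * np.pi * bounds[k + 1] * L
                dx = mids[k] - mids[k + 1]
                pairs.append((base + k, base + k + 1, a / dx))

        self.spine_head_elems = np.empty((self.spine_index.size, N_HEAD_SLABS), int)
        self.spine_influx_elem = np.empty(self.spine_index.size, int)
        head_x = np.pi * SPINE_HEAD_DIAM**2 / 4.0
        neck_x = np.pi * SPINE_NECK_DIAM**2 / 4.0
        dz_h = head_length / N_HEAD_SLABS
        dz_n = neck_length / N_NECK_SLABS
        for k, sp in enumerate(self.spine_index):
            base = len(volumes)
            # head slabs (outermost first: synaptic influx target), then neck
            for _ in range(N_HEAD_SLABS):
                volumes.append(head_x * dz_h)
                memb_area.append(np.pi * SPINE_HEAD_DIAM * dz_h)
                is_spine.append(True)
            for _ in range(N_NECK_SLABS):
                volumes.append(neck_x * dz_n)
                memb_area.append(np.pi * SPINE_NECK_DIAM * dz_n)
                is_spine.append(True)
            self.spine_head_elems[k] = base + np.arange(N_HEAD_SLABS)
            self.spine_influx_elem[k] = base
            for j in range(N_HEAD_SLABS - 1):
                pairs.append((base + j, base + j + 1, head_x / dz_h))
            pairs.append(
                (base + N_HEAD_SLABS - 1, base + N_HEAD_SLABS, neck_x / (dz_h / 2 + dz_n / 2))
            )
            for j in range(N_NECK_SLABS - 1):
                i0 = base + N_HEAD_SLABS + j
                pairs.append((i0, i0 + 1, neck_x / dz_n))
            shell0 = seg_elem0[int(spines.segment[sp])]
            last_neck = base + N_HEAD_SLABS + N_NECK_SLABS - 1
            pairs.append((last_neck, shell0, neck_x / (dz_n / 2 + SUBMEMBRANE_UM / 2)))

        self.volumes = np.asarray(volumes)
        self.memb_area = np.asarray(memb_area)
        self.is_spine = np.asarray(is_spine, dtype=bool)
        self.pair_i = np.array([p[0] for p in pairs], dtype=np.int64)
        self.pair_j = np.array([p[1] for p in pairs], dtype=np.int64)
        self.pair_geom = np.array([p[2] for p in pairs])  # area/dx, µm
        self.seg_shell0 = np.array([seg_elem0[int(s)] for s in segs], dtype=np.int64)

        bufs = self.params.buffers
        self.buf_kon = np.array([b.k_on for b in bufs])
        self.buf_koff = np.array([b.k_off for b in bufs])
        self.buf_total = np.array([b.total_um for b in bufs])
        self.buf_d = np.array([b.d_coef for b in bufs])

        # pump capacity per element (µM µm^3/ms at saturation) and the
        # balancing leak at baseline
        p = self.params
        self.pmca_cap = p.pmca.vmax * self.memb_area
        self.ncx_cap = np.where(self.is_spine, p.ncx.vmax * self.memb_area, 0.0)
        c0 = p.baseline_um
        self.leak = self.pmca_cap * c0 / (c0 + p.pmca.km) + self.ncx_cap * c0 / (
            c0 + p.ncx.km
        )

    @property
    def n_elements(self) -> int:
        return int(self.volumes.size)

    @property
    def n_spines(self) -> int:
        return int(self.spine_index.size)

    def resting_state(self) -> CalciumState:
        return resting_state(self)

    def spine_calcium(self, state: CalciumState) -> np.ndarray:
        """Volume-weighted mean head-slab free calcium per spine (µM)."""
        idx = self.spine_head_elems
        v = self.volumes[idx]
        return (state.ca[idx] * v).sum(axis=1) / v.sum(axis=1)

    def shell_calcium(self, state: CalciumState) -> np.ndarray:
        """Submembrane-shell free calcium per modelled segment (µM)."""
        return state.ca[self.seg_shell0]


def resting_state(model: CalciumModel) -> CalciumState:
    """Buffer-binding equilibrium at the baseline free calcium.

    The 1:1 mass-action equilibrium has the closed form
    ``bound = total * C / (C + Kd)``; with the balancing leak this is an
    exact fixed point of :func:`step_calcium`.
    """
    c0 = model.params.baseline_um
    n = model.n_elements
    ca = np.full(n, c0)
    kd = model.buf_koff / model.buf_kon
    bound = (model.buf_total * c0 / (c0 + kd))[:, None] * np.ones((1, n))
    free = model.buf_total[:, None] - bound
    return CalciumState(ca, free.copy(), bound.copy())


@njit(cache=True)
def _sources_half(ca, influx, h, volumes, pmca_cap, pmca_km, ncx_cap, ncx_km, leak):
    """Half-step of the sources/sinks: influx, pumps, balancing leak."""
    for i in range(ca.size):
        c = ca[i]
        pump = pmca_cap[i] * c / (c + pmca_km) + ncx_cap[i] * c / (c + ncx_km)
        d = h * (influx[i] + leak[i] - pump) / volumes[i]
        if d < -c:  # a pump is a sink and may not overdraw the element
            d = -c
        ca[i] += d


@njit(cache=True)
def _reaction_half(ca, buf_free, buf_bound, h, buf_kon, buf_koff):
    """Half-step of mass-action binding, linearised backward Euler (stable
    for the stiff binding kinetics), with overshoot guards."""
    for b in range(buf_kon.size):
        kon = buf_kon[b]
        koff = buf_koff[b]
        for i in range(ca.size):
            flux = kon * ca[i] * buf_free[b, i] - koff * buf_bound[b, i]
            denom = 1.0 + h * (kon * (ca[i] + buf_free[b, i]) + koff)
            d = flux * h / denom
            if d > 0.0:
                if d > ca[i]:
                    d = ca[i]
                if d > buf_free[b, i]:
                    d = buf_free[b, i]
            elif d < -buf_bound[b, i]:
                d = -buf_bound[b, i]
            ca[i] -= d
            buf_free[b, i] -= d
            buf_bound[b, i] += d


@njit(cache=True)
def _ca_step_kernel(
    ca, buf_free, buf_bound, influx, dt,
    volumes, pair_i, pair_j, pair_geom,
    buf_kon, buf_koff, buf_d, d_ca,
    pmca_cap, pmca_km, ncx_cap, ncx_km, leak,
):
    n = ca.size
    n_buf = buf_kon.size
    h = dt / 2.0
    # symmetric (Strang) composition: half source/sink, half reaction,
    # full diffusion, half reaction, half source/sink — cancels the leading
    # splitting error so the pulse response converges cleanly in dt
    _sources_half(ca, influx, h, volumes, pmca_cap, pmca_km, ncx_cap, ncx_km, leak)
    _reaction_half(ca, buf_free, buf_bound, h, buf_kon, buf_koff)
    # diffusion (full step): free calcium, then the free and bound forms of
    # the mobile buffers
    m = pair_i.size
    for k in range(m):
        i, j = pair_i[k], pair_j[k]
        f = d_ca * pair_geom[k] * (ca[i] - ca[j]) * dt
        ca[i] -= f / volumes[i]
        ca[j] += f / volumes[j]
    for b in range(n_buf):
        if buf_d[b] <= 0.0:
            continue
        for k in range(m):
            i, j = pair_i[k], pair_j[k]
            f = buf_d[b] * pair_geom[k] * (buf_free[b, i] - buf_free[b, j]) * dt
            buf_free[b, i] -= f / volumes[i]
            buf_free[b, j] += f / volumes[j]
            f = buf_d[b] * pair_geom[k] * (buf_bound[b, i] - buf_bound[b, j]) * dt
            buf_bound[b, i] -= f / volumes[i]
            buf_bound[b, j] += f / volumes[j]
    _reaction_half(ca, buf_free, buf_bound, h, buf_kon, buf_koff)
    _sources_half(ca, influx, h, volumes, pmca_cap, pmca_km, ncx_cap, ncx_km, leak)
    # clamp tiny negative round-off; genuine negatives are caught by caller
    ok = True
    for i in range(n):
        if ca[i] < 0.0:
            if ca[i] > -1e-9:
                ca[i] = 0.0
            else:
                ok = False
    return ok


def step_calcium(
    model: CalciumModel,
    state: CalciumState,
    influx: np.ndarray,
    dt: float = 0.025,
    pumps: bool = True,
) -> CalciumState:
    """Advance the calcium system one step of ``dt`` ms (returns new state).

    ``influx`` is the calcium source per element in µM µm^3/ms (current
    already converted to a volumetric flux).  Operator order per step:
    influx & extrusion, buffer reaction, diffusion.  Raises if a
    concentration goes negative (dt too large for the parameters).
    """
    if dt > 0.05:
        raise ValueError("calcium step must be <= 0.05 ms")
    if influx.shape != state.ca.shape:
        raise ValueError("influx must have one entry per element")
    new = state.copy()
    pmca_cap = model.pmca_cap if pumps else np.zeros_like(model.pmca_cap)
    ncx_cap = model.ncx_cap if pumps else np.zeros_like(model.ncx_cap)
    leak = model.leak if pumps else np.zeros_like(model.leak)
    ok = _ca_step_kernel(
        new.ca, new.buf_free, new.buf_bound, np.ascontiguousarray(influx, float),
        dt, model.volumes, model.pair_i, model.pair_j, model.pair_geom,
        model.buf_kon, model.buf_koff, model.buf_d, model.params.d_ca,
        pmca_cap, model.params.pmca.km, ncx_cap, model.params.ncx.km, leak,
    )
    if not ok:
        raise RuntimeError(
            "negative calcium concentration after a step; decrease dt or "
            "soften buffer kinetics"
        )
    return new
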