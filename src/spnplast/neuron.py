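"""Reduced electrical model of a spiny projection neuron.

Passive multicompartment cable (optimised SPN passive constants: RM = 6.02
Ohm m^2, CM = 0.011 F/m^2, RA = 1.3 Ohm m) with explicit spine neck/head
compartments, a minimal two-conductance spiking mechanism at the soma (fast
inward + delayed outward, Boltzmann steady states), dual-exponential
AMPA/NMDA/GABA_A synapses with a voltage-dependent magnesium block on NMDA,
and one lumped high-voltage-activated calcium conductance whose current
feeds the calcium model only.

Internal unit system: mV, ms, nF, µS (so µS·mV = nA), µm.  Integration is a
fixed-step implicit (backward-Euler) update on the compartment tree; gating
variables and the magnesium block are evaluated at the previous step's
voltage, conductances enter the matrix diagonal, so the stiff cable part is
unconditionally stable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .morphology import (
    SPINE_HEAD_DIAM,
    SPINE_HEAD_LEN,
    SPINE_NECK_DIAM,
    SPINE_NECK_LEN,
    Morphology,
    SpineSet,
)

__all__ = [
    "PassiveParams",
    "SynapseParams",
    "SomaSpikeParams",
    "VGCCParams",
    "InhibitionLayout",
    "ElectricalModel",
    "nmda_open_fraction",
    "build_electrical_model",
]

CM_NF_PER_UM2 = 1.1e-5      # 0.011 F/m^2 in nF/µm^2
GL_US_PER_UM2 = 1.661e-7    # 1/6.02 S/m^2 in µS/µm^2
RA_MOHM_UM = 1.3            # 1.3 Ohm m: axial r = 1.3 * L/A in MOhm (L µm, A µm^2)


@dataclass(frozen=True)
class PassiveParams:
    """Passive membrane constants (optimised values for the SPN)."""

    rm: float = 6.02       # Ohm m^2
    cm: float = 0.011      # F/m^2
    ra: float = 1.3        # Ohm m
    e_leak: float = -80.0  # mV

    def __post_init__(self):
        if min(self.rm, self.cm, self.ra) <= 0:
            raise ValueError("passive constants must be positive")

    @property
    def cm_nf_per_um2(self) -> float:
        return self.cm * 1e-12 * 1e9  # F/m^2 -> nF/µm^2

    @property
    def gl_us_per_um2(self) -> float:
        return (1.0 / self.rm) * 1e-12 * 1e6  # S/m^2 -> µS/µm^2

    @property
    def tau_m_ms(self) -> float:
        return self.rm * self.cm * 1e3  # s -> ms


@dataclass(frozen=True)
class SynapseParams:
    """Dual-exponential synaptic channels (conductance normalised so the
    peak equals gmax x weight).  Conductances in nS, taus in ms, E in mV.

    The AMPA/NMDA kinetics follow the corticostriatal literature the model
    is constrained by; NMDA carries a fixed fraction of its current as
    calcium.  GABA_A reverses at -60 mV (shunting relative to the -80 mV
    resting potential of SPNs).
    """

    ampa_gmax: float = 0.3
    ampa_tau_rise: float = 1.1
    ampa_tau_decay: float = 5.75
    ampa_erev: float = 0.0
    nmda_gmax: float = 0.15
    nmda_tau_rise: float = 2.2
    nmda_tau_decay: float = 60.0
    nmda_erev: float = 0.0
    nmda_mg_mm: float = 1.0
    nmda_mg_scale: float = 3.57   # mM, Mg unbinding scale of the block
    nmda_mg_slope: float = 0.062  # 1/mV, voltage steepness of the block
    nmda_ca_fraction: float = 0.05
    nmda_saturation: float = 1.0  # cap on normalised activation (receptor pool)
    gaba_gmax: float = 1.2
    gaba_tau_rise: float = 0.5
    gaba_tau_decay: float = 7.5
    gaba_erev: float = -60.0

    def __post_init__(self):
        for r, d in (
            (self.ampa_tau_rise, self.ampa_tau_decay),
            (self.nmda_tau_rise, self.nmda_tau_decay),
            (self.gaba_tau_rise, self.gaba_tau_decay),
        ):
            if not d > r > 0:
                raise ValueError("need decay tau > rise tau > 0")


@dataclass(frozen=True)
class SomaSpikeParams:
    """Minimal spiking mechanism: fast inward current with instantaneous
    Boltzmann activation, delayed outward current with first-order gating."""

    g_fast: float = 0.6      # µS
    e_fast: float = 50.0     # mV
    fast_half: float = -25.0  # mV
    fast_slope: float = 4.0  # mV
    g_slow: float = 2.0      # µS
    e_slow: float = -90.0    # mV
    slow_half: float = -25.0  # mV
    slow_slope: float = 4.0  # mV
    slow_tau: float = 2.0    # ms
    spike_threshold: float = -20.0  # mV, upward crossing marks a spike


@dataclass(frozen=True)
class VGCCParams:
    """Lumped high-voltage-activated calcium conductance.

    Stands in for the several VGCC subtypes of the full model; instantaneous
    Boltzmann activation, ohmic driving force.  Its current is routed to the
    calcium model only (no feedback onto the voltage equation).
    """

    g_spine: float = 0.02e-3  # µS per spine head (0.02 nS)
    g_dend_per_um2: float = 1.0e-7  # µS/µm^2 on dendritic shafts
    e_ca: float = 45.0        # mV
    half: float = -5.0        # mV (steep HVA activation, ~0 at rest)
    slope: float = 4.0        # mV

    def activation(self, v):
        return 1.0 / (1.0 + np.exp(-(np.asarray(v) - self.half) / self.slope))


@dataclass(frozen=True)
class InhibitionLayout:
    """GABA_A synapses on dendritic shafts: 4 per compartment, driven by
    fast-spiking interneurons within 80 µm of the soma and low-threshold-
    spiking interneurons beyond."""

    synapses_per_compartment: int = 4
    fsi_rate_hz: float = 12.0
    ltsi_rate_hz: float = 8.0
    proximal_cutoff_um: float = 80.0


def nmda_open_fraction(
    v, mg_mm: float = 1.0, scale: float = 3.57, slope: float = 0.062
):
    """Fraction of NMDA conductance unblocked by magnesium at voltage v (mV).

    Standard single-exponential voltage dependence of the block:
    ``1 / (1 + [Mg]/scale * exp(-slope*V))`` — sigmoidal and monotone
    increasing in V, ~0.04 at -70 mV with 1 mM Mg.
    """
    v = np.asarray(v, dtype=float)
    frac = 1.0 / (1.0 + (mg_mm / scale) * np.exp(-slope * v))
    return frac if frac.ndim else float(frac)


@dataclass
class ElectricalModel:
    """Flat compartment-tree arrays ready for the implicit cable solver.

    Compartments 0..n_seg-1 are the morphology segments (0 = soma); each
    assigned spine contributes a neck then a head compartment, so parents
    always precede children (Hines ordering).
    """

    morph: Morphology
    spines: SpineSet
    spine_index: np.ndarray      # indices into spines of the modelled spines
    parent: np.ndarray           # per compartment
    c_nf: np.ndarray             # capacitance per compartment
    gl_us: np.ndarray            # leak conductance per compartment
    g_axial: np.ndarray          # coupling to parent (µS), 0 for root
    area_um2: np.ndarray
    spine_neck_comp: np.ndarray  # compartment index of each modelled spine's neck
    spine_head_comp: np.ndarray  # ... and head
    e_leak: float
    passive: PassiveParams

    @property
    def n_comp(self) -> int:
        return int(self.parent.size)

    @property
    def n_segments(self) -> int:
        return self.morph.n_segments

    @property
    def n_spines(self) -> int:
        return int(self.spine_head_comp.size)


def _cyl_area(diam, length):
    return np.pi * diam * length


def _axial_g(length_a, diam_a, length_b, diam_b, ra=RA_MOHM_UM):
    """Series half-cylinder axial conductance between compartment centres (µS)."""
    area_a = np.pi * diam_a**2 / 4.0
    area_b = np.pi * diam_b**2 / 4.0
    r = ra * (length_a / 2.0 / area_a + length_b / 2.0 / area_b)  # MOhm
    return 1.0 / r


def build_electrical_model(
    morph: Morphology,
    spines: SpineSet,
    spine_index=None,
    passive: PassiveParams | None = None,
) -> ElectricalModel:
    """Assemble compartment arrays for the morphology plus selected spines.

    ``spine_index`` selects which spines get explicit electrical compartments
    (normally the spines that receive a spike train); defaults to all.
    """
    passive = passive or PassiveParams()
    if spine_index is None:
        spine_index = np.arange(spines.n_spines)
    spine_index = np.asarray(spine_index, dtype=int)

    n_seg = morph.n_segments
    n_comp = n_seg + 2 * spine_index.size
    parent = np.empty(n_comp, dtype=np.int64)
    length = np.empty(n_comp)
    diam = np.empty(n_comp)
    parent[:n_seg] = morph.parent
    length[:n_seg] = morph.length
    diam[:n_seg] = morph.diameter

    neck_comp = np.empty(spine_index.size, dtype=np.int64)
    head_comp = np.empty(spine_index.size, dtype=np.int64)
    for k, sp in enumerate(spine_index):
        neck = n_seg + 2 * k
        head = neck + 1
        parent[neck] = spines.segment[sp]
        parent[head] = neck
        length[neck], diam[neck] = SPINE_NECK_LEN, SPINE_NECK_DIAM
        length[head], diam[head] = SPINE_HEAD_LEN, SPINE_HEAD_DIAM
        neck_comp[k], head_comp[k] = neck, head

    area = _cyl_area(diam, length)
    c_nf = area * passive.cm_nf_per_um2
    gl = area * passive.gl_us_per_um2
    g_ax = np.zeros(n_comp)
    for i in range(1, n_comp):
        p = parent[i]
        g_ax[i] = _axial_g(length[i], diam[i], length[p], diam[p], passive.ra)

    return ElectricalModel(
        morph=morph,
        spines=spines,
        spine_index=spine_index,
        parent=parent,
        c_nf=c_nf,
        gl_us=gl,
        g_axial=g_ax,
        area_um2=area,
        spine_neck_comp=neck_comp,
        spine_head_comp=head_comp,
        e_leak=passive.e_leak,
        passive=passive,
    )


def dual_exp_norm(tau_rise: float, tau_decay: float) -> float:
    """Normalisation so the dual-exponential difference peaks at 1."""
    tp = (
        np.log(tau_decay / tau_rise)
        * tau_rise
        * tau_decay
        / (tau_decay - tau_rise)
    )
    return 1.0 / (np.exp(-tp / tau_decay) - np.exp(-tp / tau_rise))
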