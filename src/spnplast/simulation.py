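"""Coupled voltage / calcium / plasticity simulation of the reduced SPN.

One compiled inner loop advances the implicit cable solve (Hines elimination
on the compartment tree), the dual-exponential synaptic conductances, the
minimal spiking soma, the spine/dendrite calcium system and the online
plasticity rule, with the synaptic weight of each spine multiplying its
AMPA and NMDA conductances so potentiation feeds back onto the electrical
response within the same experiment.

Voltage step 0.05 ms (implicit, unconditionally stable on the stiff cable);
calcium and plasticity sub-step at half that.  Spine calcium and weights are
recorded every ``record_dt`` (default 1 ms); somatic voltage at full
resolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from . import calcium as ca_mod
from .calcium import CURRENT_TO_FLUX, CalciumModel, CalciumParams
from .morphology import ClusterMapping, Morphology, SpineSet
from .neuron import (
    InhibitionLayout,
    PassiveParams,
    SomaSpikeParams,
    SynapseParams,
    VGCCParams,
    build_electrical_model,
    dual_exp_norm,
)
from .plasticity import PlasticityParams, plasticity_step
from .spiketrains import SpikeTrain, TrialSet, generate_poisson_inhibition

__all__ = [
    "SimulationConfig",
    "SimResult",
    "VoltageTrace",
    "SPNSimulation",
    "simulate_voltage",
]


@dataclass(frozen=True)
class SimulationConfig:
    dt_v: float = 0.05        # ms, voltage step (must be <= 0.1)
    ca_substeps: int = 2      # calcium substeps per voltage step
    record_dt: float = 1.0    # ms, recording stride for calcium/weights
    v_abort: float = 200.0    # |mV| blow-up bound
    record_voltage: bool = False  # also record every compartment's V

    def __post_init__(self):
        if self.dt_v > 0.1:
            raise ValueError("voltage step must be <= 0.1 ms")
        if self.dt_v / self.ca_substeps > 0.05:
            raise ValueError("calcium substep must be <= 0.05 ms")


@dataclass
class VoltageTrace:
    """Per-compartment membrane potential (mV) on the recording grid."""

    t_ms: np.ndarray
    v: np.ndarray          # (n_rec, n_comp)
    soma_t_ms: np.ndarray  # full-resolution soma time grid
    soma_v: np.ndarray
    spike_times_s: np.ndarray


@dataclass
class SimResult:
    """Recorded trajectories of one experiment."""

    t_ms: np.ndarray          # recording grid
    ca_spine: np.ndarray      # (n_rec, n_spines) µM
    weights: np.ndarray       # (n_rec, n_spines)
    soma_v: np.ndarray        # full-resolution somatic voltage
    soma_t_ms: np.ndarray
    spike_times_s: np.ndarray
    spine_index: np.ndarray   # spine ids, column order of ca_spine/weights
    train_ids: np.ndarray     # train driving each column
    trial_windows: list       # (t0_s, t1_s) per trial
    v_all: np.ndarray | None = None

    def weight_at(self, t_s: float) -> np.ndarray:
        k = np.searchsorted(self.t_ms, t_s * 1e3, side="right") - 1
        return self.weights[max(k, 0)]

    def per_trial_dw(self) -> np.ndarray:
        """(n_trials, n_spines) weight change over each trial window."""
        out = np.empty((len(self.trial_windows), self.weights.shape[1]))
        for k, (t0, t1) in enumerate(self.trial_windows):
            out[k] = self.weight_at(t1) - self.weight_at(t0)
        return out


@njit(cache=True)
def _simulate_kernel(
    n_steps, dt_v, ca_substeps,
    # cable
    parent, g_ax, c_nf, gl, e_leak, i_inject,
    # soma spiking mechanism
    g_fast, e_fast, fast_half, fast_slope,
    g_slow, e_slow, slow_half, slow_slope, slow_tau, spike_thresh,
    # excitatory synapses (one per modelled spine, on its head compartment)
    exc_comp, ev_exc_step, ev_exc_syn,
    fA_r, fA_d, normA, gA, fN_r, fN_d, normN, gN, nmda_sat,
    mg_coef, mg_slope, f_ca_nmda,
    # GABA synapses
    gaba_comp, ev_gab_step, ev_gab_syn, fG_r, fG_d, normG, gG, eG,
    # lumped VGCC
    g_ca_head, g_ca_seg, seg_comp, e_ca, vg_half, vg_slope,
    # calcium system
    enable_calcium, ca, buf_free, buf_bound,
    volumes, pair_i, pair_j, pair_geom,
    buf_kon, buf_koff, buf_d, d_ca,
    pmca_cap, pmca_km, ncx_cap, ncx_km, leak,
    spine_influx_elem, seg_shell0, head_elem, head_w,
    # plasticity
    w, k_ad, k_ap,
    t_ad, t_ap, dur_d, dur_p, g_p, g_p_max, g_d, g_d_max, w_min, w_max,
    # recording
    rec_stride, ca_rec, w_rec, v_soma, v_rec, record_all_v,
    spike_steps, v_abort,
):
    n_comp = parent.size
    n_exc = exc_comp.size
    n_gab = gaba_comp.size
    n_mseg = seg_comp.size
    dt_ca = dt_v / ca_substeps

    v = np.full(n_comp, e_leak)
    yrA = np.zeros(n_exc); ydA = np.zeros(n_exc)
    yrN = np.zeros(n_exc); ydN = np.zeros(n_exc)
    yrG = np.zeros(n_gab); ydG = np.zeros(n_gab)
    slow_n = 1.0 / (1.0 + np.exp(-(e_leak - slow_half) / slow_slope))

    diag = np.empty(n_comp)
    rhs = np.empty(n_comp)
    influx = np.zeros(ca.size)
    g_nmda_eff = np.zeros(n_exc)

    pe = 0  # exc event pointer
    pg = 0
    n_spk = 0
    v_soma_prev = v[0]
    rec_idx = 0

    for step in range(n_steps):
        # ---- synaptic state decay + events landing on this step
        for s in range(n_exc):
            yrA[s] *= fA_r; ydA[s] *= fA_d
            yrN[s] *= fN_r; ydN[s] *= fN_d
        for s in range(n_gab):
            yrG[s] *= fG_r; ydG[s] *= fG_d
        while pe < ev_exc_step.size and ev_exc_step[pe] == step:
            s = ev_exc_syn[pe]
            yrA[s] += 1.0; ydA[s] += 1.0
            yrN[s] += 1.0; ydN[s] += 1.0
            pe += 1
        while pg < ev_gab_step.size and ev_gab_step[pg] == step:
            s = ev_gab_syn[pg]
            yrG[s] += 1.0; ydG[s] += 1.0
            pg += 1

        # ---- assemble implicit system: diag*V+ - g_ax couplings = rhs
        for i in range(n_comp):
            diag[i] = c_nf[i] / dt_v + gl[i]
            rhs[i] = c_nf[i] / dt_v * v[i] + gl[i] * e_leak + i_inject[i]
        for i in range(1, n_comp):
            diag[i] += g_ax[i]
            diag[parent[i]] += g_ax[i]
        # soma spiking conductances (gating at previous V)
        m_inf = 1.0 / (1.0 + np.exp(-(v[0] - fast_half) / fast_slope))
        n_inf = 1.0 / (1.0 + np.exp(-(v[0] - slow_half) / slow_slope))
        slow_n += (n_inf - slow_n) * (1.0 - np.exp(-dt_v / slow_tau))
        gf = g_fast * m_inf
        gs = g_slow * slow_n
        diag[0] += gf + gs
        rhs[0] += gf * e_fast + gs * e_slow
        # synapses (conductance in diagonal; E_exc = 0 adds nothing to rhs)
        for s in range(n_exc):
            c = exc_comp[s]
            g_ampa = gA * w[s] * normA * (ydA[s] - yrA[s])
            act_n = normN * (ydN[s] - yrN[s])
            if act_n > nmda_sat:  # receptor-pool saturation
                act_n = nmda_sat
            block = 1.0 / (1.0 + mg_coef * np.exp(-mg_slope * v[c]))
            g_nmda = gN * w[s] * act_n * block
            g_nmda_eff[s] = g_nmda
            diag[c] += g_ampa + g_nmda
        for s in range(n_gab):
            c = gaba_comp[s]
            g = gG * normG * (ydG[s] - yrG[s])
            diag[c] += g
            rhs[c] += g * eG

        # ---- Hines solve (children have larger indices)
        for i in range(n_comp - 1, 0, -1):
            p = parent[i]
            f = g_ax[i] / diag[i]
            diag[p] -= f * g_ax[i]
            rhs[p] += f * rhs[i]
        v[0] = rhs[0] / diag[0]
        for i in range(1, n_comp):
            v[i] = (rhs[i] + g_ax[i] * v[parent[i]]) / diag[i]

        vmax = np.abs(v).max()
        if vmax > v_abort or vmax != vmax:  # out of bounds or NaN
            return -(step + 1), n_spk, rec_idx
        if (
            v_soma_prev < spike_thresh
            and v[0] >= spike_thresh
            and n_spk < spike_steps.size
        ):
            spike_steps[n_spk] = step
            n_spk += 1
        v_soma_prev = v[0]
        v_soma[step] = v[0]

        # ---- calcium influx currents at the new voltages, then substeps
        if enable_calcium:
            for i in range(influx.size):
                influx[i] = 0.0
            for s in range(n_exc):
                c = exc_comp[s]
                i_nmda_ca = f_ca_nmda * g_nmda_eff[s] * (0.0 - v[c])  # inward > 0
                mv = 1.0 / (1.0 + np.exp(-(v[c] - vg_half) / vg_slope))
                i_vgcc = g_ca_head * mv * (e_ca - v[c])
                amt = i_nmda_ca + i_vgcc
                if amt > 0.0:
                    influx[spine_influx_elem[s]] += CURRENT_TO_FLUX * amt
            for q in range(n_mseg):
                c = seg_comp[q]
                mv = 1.0 / (1.0 + np.exp(-(v[c] - vg_half) / vg_slope))
                i_vgcc = g_ca_seg[q] * mv * (e_ca - v[c])
                if i_vgcc > 0.0:
                    influx[seg_shell0[q]] += CURRENT_TO_FLUX * i_vgcc
            for _sub in range(ca_substeps):
                ok = ca_mod._ca_step_kernel(
                    ca, buf_free, buf_bound, influx, dt_ca,
                    volumes, pair_i, pair_j, pair_geom,
                    buf_kon, buf_koff, buf_d, d_ca,
                    pmca_cap, pmca_km, ncx_cap, ncx_km, leak,
                )
                if not ok:
                    return -(1000000000 + step + 1), n_spk, rec_idx
                # plasticity at the calcium step
                for s in range(n_exc):
                    csp = (
                        ca[head_elem[s, 0]] * head_w[0]
                        + ca[head_elem[s, 1]] * head_w[1]
                    )
                    w[s], k_ad[s], k_ap[s] = plasticity_step(
                        csp, w[s], k_ad[s], k_ap[s], dt_ca,
                        t_ad, t_ap, dur_d, dur_p,
                        g_p, g_p_max, g_d, g_d_max, w_min, w_max,
                    )

        # ---- recording
        if (step + 1) % rec_stride == 0:
            for s in range(n_exc):
                ca_rec[rec_idx, s] = (
                    ca[head_elem[s, 0]] * head_w[0]
                    + ca[head_elem[s, 1]] * head_w[1]
                ) if enable_calcium else 0.0
                w_rec[rec_idx, s] = w[s]
            if record_all_v:
                for i in range(n_comp):
                    v_rec[rec_idx, i] = v[i]
            rec_idx += 1

    return 0, n_spk, rec_idx


def _events_to_steps(trains, dt_v_ms, n_steps):
    """Flatten spike trains to (step, index) arrays sorted by step."""
    steps = []
    idx = []
    for k, tr in enumerate(trains):
        if tr is None or tr.times.size == 0:
            continue
        s = np.round(tr.times * 1e3 / dt_v_ms).astype(np.int64)
        s = s[(s >= 0) & (s < n_steps)]
        steps.append(s)
        idx.append(np.full(s.size, k, dtype=np.int64))
    if not steps:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    steps = np.concatenate(steps)
    idx = np.concatenate(idx)
    order = np.argsort(steps, kind="stable")
    return steps[order], idx[order]


class SPNSimulation:
    """Assemble and run one experiment on the reduced SPN.

    Parameters
    ----------
    morph, spines, mapping
        Morphology, placed spines and the train->spine assignment; only
        assigned spines receive electrical and calcium compartments.
    trial_set
        The global-timeline spike trains (one entry per trial); train ids
        must match the mapping.
    inhibition
        Layout of the GABA synapses; Poisson trains are generated internally
        for the full experiment duration from ``seed``.
    """

    def __init__(
        self,
        morph: Morphology,
        spines: SpineSet,
        mapping: ClusterMapping,
        trial_set: TrialSet,
        passive: PassiveParams | None = None,
        synapse: SynapseParams | None = None,
        soma: SomaSpikeParams | None = None,
        vgcc: VGCCParams | None = None,
        inhibition: InhibitionLayout | None = None,
        ca_params: CalciumParams | None = None,
        plasticity: PlasticityParams | None = None,
        config: SimulationConfig | None = None,
        seed: int = 0,
        w0: float = 1.0,
        enable_calcium: bool = True,
        enable_inhibition: bool = True,
        i_inject_nA: dict | None = None,
    ):
        self.morph = morph
        self.spines = spines
        self.mapping = mapping
        self.trial_set = trial_set
        self.passive = passive or PassiveParams()
        self.synapse = synapse or SynapseParams()
        self.soma = soma or SomaSpikeParams()
        self.vgcc = vgcc or VGCCParams()
        self.inhibition = inhibition or InhibitionLayout()
        self.ca_params = ca_params or CalciumParams()
        self.plasticity = plasticity or PlasticityParams()
        self.config = config or SimulationConfig()
        self.seed = seed
        self.w0 = w0
        self.enable_calcium = enable_calcium
        self.enable_inhibition = enable_inhibition
        self.i_inject_nA = dict(i_inject_nA or {})  # compartment -> constant nA

        self.emodel = build_electrical_model(
            morph, spines, mapping.spine_ids, self.passive
        )
        self.camodel = CalciumModel(
            morph, spines, mapping.spine_ids, self.ca_params
        )

    def _excitatory_trains(self):
        """Per modelled spine, the global-timeline spike times (merged trials)."""
        by_train: dict[int, list] = {int(t): [] for t in self.mapping.train_ids}
        for trial_trains in self.trial_set.trains:
            for tr in trial_trains:
                if int(tr.train_id) in by_train:
                    by_train[int(tr.train_id)].append(tr.times)
        out = []
        t_end = self.trial_set.total_duration
        for tid in self.mapping.train_ids:
            times = np.sort(np.concatenate(by_train[int(tid)] or [np.empty(0)]))
            out.append(SpikeTrain(int(tid), times, 0.0, max(t_end, 1.0)))
        return out

    def _gaba_trains(self, duration_s):
        layout = self.inhibition
        n_per = layout.synapses_per_compartment
        mid = self.morph.midpoint_distance
        comps = []
        rates = []
        for seg in range(1, self.morph.n_segments):
            rate = (
                layout.fsi_rate_hz
                if mid[seg] <= layout.proximal_cutoff_um
                else layout.ltsi_rate_hz
            )
            for _ in range(n_per):
                comps.append(seg)
                rates.append(rate)
        ss = np.random.SeedSequence([self.seed, 911]).spawn(len(comps))
        trains = [
            generate_poisson_inhibition(
                r, duration_s, int(s.generate_state(1)[0] % (2**31)), train_id=k
            )
            for k, (r, s) in enumerate(zip(rates, ss))
        ]
        return np.asarray(comps, np.int64), trains

    def run(self) -> SimResult:
        cfg = self.config
        syn = self.synapse
        em = self.emodel
        cm = self.camodel
        duration_s = self.trial_set.total_duration
        n_steps = int(round(duration_s * 1e3 / cfg.dt_v))
        rec_stride = max(1, int(round(cfg.record_dt / cfg.dt_v)))
        n_rec = n_steps // rec_stride
        n_exc = em.n_spines

        exc_trains = self._excitatory_trains()
        ev_exc_step, ev_exc_syn = _events_to_steps(exc_trains, cfg.dt_v, n_steps)
        if self.enable_inhibition:
            gaba_comp, gtr = self._gaba_trains(duration_s)
            ev_gab_step, ev_gab_syn = _events_to_steps(gtr, cfg.dt_v, n_steps)
        else:
            gaba_comp = np.empty(0, np.int64)
            ev_gab_step = np.empty(0, np.int64)
            ev_gab_syn = np.empty(0, np.int64)

        state = cm.resting_state()
        head_elem = np.ascontiguousarray(cm.spine_head_elems)
        hv = cm.volumes[head_elem[0]] if n_exc else np.array([1.0, 1.0])
        head_w = hv / hv.sum()

        seg_comp = cm.segments.astype(np.int64)
        g_ca_seg = self.vgcc.g_dend_per_um2 * em.area_um2[seg_comp]

        ca_rec = np.zeros((n_rec, n_exc))
        w_rec = np.zeros((n_rec, n_exc))
        v_soma = np.zeros(n_steps)
        v_rec = (
            np.zeros((n_rec, em.n_comp))
            if cfg.record_voltage
            else np.zeros((1, em.n_comp))
        )
        spike_steps = np.zeros(n_steps // 10 + 16, np.int64)
        w = np.full(n_exc, self.w0)
        k_ad = np.zeros(n_exc, np.int64)
        k_ap = np.zeros(n_exc, np.int64)
        i_inject = np.zeros(em.n_comp)
        for comp, amp in self.i_inject_nA.items():
            i_inject[int(comp)] = amp

        pp = self.plasticity
        status, n_spk, rec_done = _simulate_kernel(
            n_steps, cfg.dt_v, cfg.ca_substeps,
            em.parent, em.g_axial, em.c_nf, em.gl_us, em.e_leak, i_inject,
            self.soma.g_fast, self.soma.e_fast, self.soma.fast_half,
            self.soma.fast_slope, self.soma.g_slow, self.soma.e_slow,
            self.soma.slow_half, self.soma.slow_slope, self.soma.slow_tau,
            self.soma.spike_threshold,
            em.spine_head_comp, ev_exc_step, ev_exc_syn,
            np.exp(-cfg.dt_v / syn.ampa_tau_rise),
            np.exp(-cfg.dt_v / syn.ampa_tau_decay),
            dual_exp_norm(syn.ampa_tau_rise, syn.ampa_tau_decay),
            syn.ampa_gmax * 1e-3,
            np.exp(-cfg.dt_v / syn.nmda_tau_rise),
            np.exp(-cfg.dt_v / syn.nmda_tau_decay),
            dual_exp_norm(syn.nmda_tau_rise, syn.nmda_tau_decay),
            syn.nmda_gmax * 1e-3, syn.nmda_saturation,
            syn.nmda_mg_mm / syn.nmda_mg_scale, syn.nmda_mg_slope,
            syn.nmda_ca_fraction,
            gaba_comp, ev_gab_step, ev_gab_syn,
            np.exp(-cfg.dt_v / syn.gaba_tau_rise),
            np.exp(-cfg.dt_v / syn.gaba_tau_decay),
            dual_exp_norm(syn.gaba_tau_rise, syn.gaba_tau_decay),
            syn.gaba_gmax * 1e-3, syn.gaba_erev,
            self.vgcc.g_spine, g_ca_seg, seg_comp,
            self.vgcc.e_ca, self.vgcc.half, self.vgcc.slope,
            self.enable_calcium, state.ca, state.buf_free, state.buf_bound,
            cm.volumes, cm.pair_i, cm.pair_j, cm.pair_geom,
            cm.buf_kon, cm.buf_koff, cm.buf_d, cm.params.d_ca,
            cm.pmca_cap, cm.params.pmca.km, cm.ncx_cap, cm.params.ncx.km,
            cm.leak,
            cm.spine_influx_elem.astype(np.int64), cm.seg_shell0,
            head_elem.astype(np.int64), head_w,
            w, k_ad, k_ap, *pp.as_tuple(),
            rec_stride, ca_rec, w_rec, v_soma, v_rec, cfg.record_voltage,
            spike_steps, cfg.v_abort,
        )
        if status < 0:
            step = -status - 1
            if step >= 1000000000:
                step -= 1000000000
                raise RuntimeError(
                    f"negative calcium concentration at step {step} "
                    f"(t={step * cfg.dt_v:.2f} ms); decrease the calcium substep"
                )
            raise RuntimeError(
                f"membrane potential out of bounds at step {step} "
                f"(t={step * cfg.dt_v:.2f} ms) ; decrease dt_v"
            )
        t_rec = (np.arange(n_rec) + 1) * rec_stride * cfg.dt_v
        return SimResult(
            t_ms=t_rec,
            ca_spine=ca_rec,
            weights=w_rec,
            soma_v=v_soma,
            soma_t_ms=(np.arange(n_steps) + 1) * cfg.dt_v,
            spike_times_s=spike_steps[:n_spk] * cfg.dt_v * 1e-3,
            spine_index=self.mapping.spine_ids.copy(),
            train_ids=self.mapping.train_ids.copy(),
            trial_windows=list(self.trial_set.trials),
            v_all=v_rec if cfg.record_voltage else None,
        )


def simulate_voltage(
    morph: Morphology,
    spines: SpineSet,
    mapping: ClusterMapping,
    trial_set: TrialSet,
    dt: float = 0.05,
    seed: int = 0,
    inhibition: bool = True,
    **kwargs,
) -> VoltageTrace:
    """Electrical response only (calcium and plasticity switched off)."""
    sim = SPNSimulation(
        morph, spines, mapping, trial_set,
        config=SimulationConfig(dt_v=dt, record_voltage=True),
        seed=seed, enable_calcium=False, enable_inhibition=inhibition,
        **kwargs,
    )
    res = sim.run()
    return VoltageTrace(
        t_ms=res.t_ms,
        v=res.v_all,
        soma_t_ms=res.soma_t_ms,
        soma_v=res.soma_v,
        spike_times_s=res.spike_times_s,
    )
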