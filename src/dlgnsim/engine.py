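"""Event-and-clock hybrid integration engine.

One compiled kernel advances any number of two-compartment TC neurons:
gating variables by exponential Euler on per-neuron voltage lookup tables,
compartment voltages by exponential Euler with implicit self-conductance
(axon segments swept soma-outward, Gauss-Seidel style), and synapses by a
delayed event queue binned at the integration step.  The same machinery
serves single-neuron current-clamp protocols (one neuron, no synapses) and
full network runs with retinal afferents plus all-to-all feedback loops.

Synaptic events pass through per-synapse Tsodyks-Markram depression at the
source and are delivered into per-neuron dual-exponential receptor states
(AMPA, NMDA, GABA) after the synaptic delay.  Spike detection is an upward
crossing of 0 mV at the soma with a 2 ms refractory period; a TC spike
immediately schedules that neuron's outgoing feedback events.

Units inside the kernel: mV, ms, uS, nA, nF, mM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from . import mechanisms as mech
from .mechanisms import (
    CA_RESTING_MM,
    DV,
    FARADAY,
    NV,
    V_MIN,
    build_gate_tables,
    ghk_factors,
)
from .params import CA_BUFFER_DEPTH_UM, NeuronParams
from .synapses import (
    AMPA_KINETICS,
    GABA_KINETICS,
    NMDA_KINETICS,
    ReceptorKinetics,
    nmda_ca_permeability,
)

__all__ = [
    "CompiledNetwork",
    "SynapseTable",
    "IntegrationError",
    "axon_segment_count",
    "ac_length_constant_um",
    "SPIKE_THRESHOLD_MV",
    "SPIKE_REFRACTORY_MS",
]

SPIKE_THRESHOLD_MV = 0.0
SPIKE_REFRACTORY_MS = 2.0
BLOWUP_MV = 200.0
CM_UF_CM2 = 1.0  # specific membrane capacitance, fixed


class IntegrationError(RuntimeError):
    def __init__(self, neuron: int, t_ms: float):
        self.neuron = neuron
        self.t_ms = t_ms
        super().__init__(
            f"membrane potential exceeded +-{BLOWUP_MV:.0f} mV "
            f"(neuron {neuron}, t={t_ms:.3f} ms)"
        )


def ac_length_constant_um(diam_um: float, ra: float, freq_hz: float = 100.0) -> float:
    """AC length constant of an unbranched cable (um) at ``freq_hz``."""
    return 1e5 * np.sqrt(diam_um / (4.0 * np.pi * freq_hz * ra * CM_UF_CM2))


def axon_segment_count(params: NeuronParams, freq_hz: float = 100.0) -> int:
    """Odd number of axonal segments, each no longer than 0.1 of the AC
    length constant at ``freq_hz``."""
    lam = ac_length_constant_um(params.axon_diam, params.ra, freq_hz)
    n = int(np.ceil(params.axon_L / (0.1 * lam)))
    n = max(n, 1)
    if n % 2 == 0:
        n += 1
    return n


@dataclass
class SynapseTable:
    """Flat synapse table in CSR-by-source layout.

    Sources ``0..n_sources-1`` are external (retinal) units; sources
    ``n_sources..n_sources+n_neurons-1`` are the TC neurons themselves
    (feedback loops).  ``mix_id`` indexes rows of the network's receptor-mix
    matrix; ``cls`` tags each synapse 0=retinal, 1=TRN loop, 2=cortical
    loop for homeostatic scaling.
    """

    n_sources: int
    src_ptr: np.ndarray  # int64, len n_sources + n_neurons + 1
    target: np.ndarray  # int32
    g: np.ndarray  # float64, uS (mutated by homeostasis)
    mix_id: np.ndarray  # int32
    delay_ms: np.ndarray  # float64
    u0: np.ndarray  # float64 (0 => no depression)
    tau_rec: np.ndarray  # float64
    cls: np.ndarray  # int8

    def __post_init__(self):
        n = self.target.size
        for a in (self.g, self.mix_id, self.delay_ms, self.u0, self.tau_rec, self.cls):
            if a.size != n:
                raise ValueError("synapse table columns must have equal length")
        if n and self.delay_ms.min() <= 0:
            raise ValueError("synaptic delays must be > 0")

    @property
    def n_synapses(self) -> int:
        return self.target.size

    @classmethod
    def empty(cls, n_sources: int, n_neurons: int) -> "SynapseTable":
        return cls(
            n_sources=n_sources,
            src_ptr=np.zeros(n_sources + n_neurons + 1, dtype=np.int64),
            target=np.zeros(0, dtype=np.int32),
            g=np.zeros(0),
            mix_id=np.zeros(0, dtype=np.int32),
            delay_ms=np.zeros(0),
            u0=np.zeros(0),
            tau_rec=np.zeros(0),
            cls=np.zeros(0, dtype=np.int8),
        )

    @classmethod
    def from_records(cls, n_sources, n_neurons, records) -> "SynapseTable":
        """records: iterable of (source, target, g, mix_id, delay_ms, u0,
        tau_rec, cls); sources >= n_sources denote TC feedback sources."""
        rec = sorted(records, key=lambda r: r[0])
        ns = len(rec)
        src = np.array([r[0] for r in rec], dtype=np.int64)
        ptr = np.zeros(n_sources + n_neurons + 1, dtype=np.int64)
        np.add.at(ptr, src + 1, 1)
        np.cumsum(ptr, out=ptr)
        return cls(
            n_sources=n_sources,
            src_ptr=ptr,
            target=np.array([r[1] for r in rec], dtype=np.int32),
            g=np.array([r[2] for r in rec], dtype=float),
            mix_id=np.array([r[3] for r in rec], dtype=np.int32),
            delay_ms=np.array([r[4] for r in rec], dtype=float),
            u0=np.array([r[5] for r in rec], dtype=float),
            tau_rec=np.array([r[6] for r in rec], dtype=float),
            cls=np.array([r[7] for r in rec], dtype=np.int8),
        )


# --------------------------------------------------------------------------
# compiled kernel
# --------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def _advance_kernel(
    n_steps, dt, t0_ms,
    # state
    VS, SG, ZSK, CAI, VA, AG, NSEG, last_spike,
    # tables
    XINF, QE, GAV, GBV,
    # per-neuron scalars
    CS, GPASS, EPAS, GNA, GK, GSK, GNAP, GAK, GH, EH, PT, PL,
    ENA, EK, CAO, QEZ, CADA, TAUR, CAINF, INVAREA, PNCA,
    CSEG, GPASA, GNAA, GKA, GAXS0, GAXSEG,
    # receptors
    SA, SB, QD, QR, NORM, EGABA, MIX, MGBLOCK,
    # events
    pending, H, slot0,
    ev_step, ev_src, ev_cursor,
    sy_ptr, sy_tgt, sy_g, sy_mix, sy_dstep, sy_R, sy_tlast, sy_u0, sy_taurec,
    n_ext_sources,
    # stimulation
    IINJ,
    # output
    spk_t, spk_i, spk_n, vrec, rec_every, varec, rec_axon,
    counters, n_corr, SGOLD, AGOLD,
):
    nn = VS.shape[0]
    inv_dv = 1.0 / DV
    for step in range(n_steps):
        t = t0_ms + step * dt
        slot = (slot0 + step) % H
        # ---- deliver queued events -----------------------------------
        for i in range(nn):
            for k in range(3):
                w = pending[i, slot, k]
                if w != 0.0:
                    SA[i, k] += w
                    SB[i, k] += w
                    pending[i, slot, k] = 0.0
        # ---- external (retinal) source spikes ------------------------
        gstep = slot0 + step  # absolute step index
        while ev_cursor[0] < ev_step.shape[0] and ev_step[ev_cursor[0]] <= gstep:
            s = ev_src[ev_cursor[0]]
            ev_cursor[0] += 1
            for jj in range(sy_ptr[s], sy_ptr[s + 1]):
                u0 = sy_u0[jj]
                if u0 > 0.0:
                    el = t - sy_tlast[jj]
                    r = 1.0 - (1.0 - sy_R[jj]) * np.exp(-el / sy_taurec[jj])
                    rel = u0 * r
                    sy_R[jj] = r * (1.0 - u0)
                    sy_tlast[jj] = t
                else:
                    rel = 1.0
                w = sy_g[jj] * rel
                if w != 0.0:
                    tgt = sy_tgt[jj]
                    dslot = (slot + sy_dstep[jj]) % H
                    m = sy_mix[jj]
                    for k in range(3):
                        if MIX[m, k] != 0.0:
                            pending[tgt, dslot, k] += w * MIX[m, k]
                counters[0] += 1
        # ---- decay receptor states -----------------------------------
        for i in range(nn):
            for k in range(3):
                SA[i, k] *= QD[k]
                SB[i, k] *= QR[k]
        # ---- integrate neurons ---------------------------------------
        for i in range(nn):
            v = VS[i]
            cai0 = CAI[i]
            z0 = ZSK[i]
            for g10 in range(10):
                SGOLD[g10] = SG[i, g10]
            # receptor conductances (voltage-independent except Mg block)
            gampa = NORM[0] * (SA[i, 0] - SB[i, 0])
            gnmda0 = NORM[1] * (SA[i, 1] - SB[i, 1])
            ggaba = NORM[2] * (SA[i, 2] - SB[i, 2])
            if gampa < 0.0:
                gampa = 0.0
            if gnmda0 < 0.0:
                gnmda0 = 0.0
            if ggaba < 0.0:
                ggaba = 0.0
            # predictor pass evaluates rates at the pre-step voltage; each
            # corrector pass re-evaluates them at the midpoint (Heun-like,
            # restores ~2nd-order spike timing at protocol dt)
            vnew = v
            cai = cai0
            z = z0
            i_t = i_l = i_nca = 0.0
            for p in range(n_corr + 1):
                v_eval = v if p == 0 else 0.5 * (v + vnew)
                cai_eval = cai0 if p == 0 else 0.5 * (cai0 + cai)
                fv = (v_eval - V_MIN) * inv_dv
                iv = int(fv)
                if iv < 0:
                    iv = 0
                elif iv > NV - 2:
                    iv = NV - 2
                fr = fv - iv
                if fr < 0.0:
                    fr = 0.0
                elif fr > 1.0:
                    fr = 1.0
                for gidx in range(10):
                    xi = XINF[i, gidx, iv] * (1.0 - fr) + XINF[i, gidx, iv + 1] * fr
                    q = QE[i, gidx, iv] * (1.0 - fr) + QE[i, gidx, iv + 1] * fr
                    SG[i, gidx] = xi + (SGOLD[gidx] - xi) * q
                zinf = 1.0 / (1.0 + (0.00043 / cai_eval) ** 4.8)
                z = zinf + (z0 - zinf) * QEZ[i]
                # channel conductances (uS)
                m3h = SG[i, 0] * SG[i, 0] * SG[i, 0] * SG[i, 1]
                n4 = SG[i, 2] ** 4
                gna = GNA[i] * m3h
                gk = GK[i] * n4
                gsk = GSK[i] * z
                gnap = GNAP[i] * SG[i, 6]
                gak = GAK[i] * (SG[i, 7] ** 4) * SG[i, 8]
                gh = GH[i] * SG[i, 5]
                # GHK factor (per unit permeability, mA/cm^2)
                ghkf = (GAV[iv] * (1.0 - fr) + GAV[iv + 1] * fr) * cai_eval - (
                    GBV[iv] * (1.0 - fr) + GBV[iv + 1] * fr
                ) * CAO[i]
                i_t = PT[i] * SG[i, 3] * SG[i, 3] * SG[i, 4] * ghkf  # inward < 0
                i_l = PL[i] * SG[i, 9] * SG[i, 9] * ghkf
                gnmda = gnmda0
                if MGBLOCK == 1:
                    gnmda *= 1.0 / (1.0 + np.exp(-0.062 * v_eval) / 3.57)
                i_nca = PNCA[i] * gnmda * ghkf
                gtot = (
                    GPASS[i] + gna + gk + gsk + gnap + gak + gh
                    + gampa + gnmda + ggaba
                )
                ge = (
                    GPASS[i] * EPAS[i]
                    + (gna + gnap) * ENA[i]
                    + (gk + gsk + gak) * EK[i]
                    + gh * EH[i]
                    + ggaba * EGABA
                )
                # GHK Ca currents enter as chord conductances toward the
                # Ca Nernst potential: same instantaneous current, but
                # implicit in V (stable under heavy bombardment)
                i_ca_all = i_t + i_l + i_nca
                e_ca = 13.319 * np.log(CAO[i] / cai_eval)
                dv_ca = v_eval - e_ca
                if dv_ca < -1.0 or dv_ca > 1.0:
                    g_ca = i_ca_all / dv_ca
                    if g_ca > 0.0:
                        gtot += g_ca
                        ge += g_ca * e_ca
                        i_ca_all = 0.0
                gax0 = GAXS0[i]
                gtot_s = gtot + gax0
                icur = -i_ca_all + IINJ[i]
                veq = (ge + gax0 * VA[i, 0] + icur) / gtot_s
                vnew = veq + (v - veq) * np.exp(-dt * gtot_s / CS[i])
                # calcium pool
                dens = (i_t + i_l + i_nca) * INVAREA[i]  # mA/cm^2
                drive = -CADA[i] * dens
                ceq = CAINF[i] + TAUR[i] * drive
                cai = ceq + (cai0 - ceq) * np.exp(-dt / TAUR[i])
                if cai < 1e-9:
                    cai = 1e-9
            ZSK[i] = z
            CAI[i] = cai
            # spike detection at the soma
            spiked = False
            if v < SPIKE_THRESHOLD_MV and vnew >= SPIKE_THRESHOLD_MV:
                if (t + dt) - last_spike[i] >= SPIKE_REFRACTORY_MS:
                    spiked = True
                    last_spike[i] = t + dt
            VS[i] = vnew
            if not (-BLOWUP_MV < vnew < BLOWUP_MV):
                return 1, i, t
            ns = NSEG[i]
            gax0 = GAXS0[i]
            # ---- axon sweep (soma outward, fresh upstream voltage) ---
            vprev = vnew
            for s in range(ns):
                va = VA[i, s]
                for gg in range(3):
                    AGOLD[gg] = AG[i, s, gg]
                va_new = va
                for p in range(n_corr + 1):
                    va_eval = va if p == 0 else 0.5 * (va + va_new)
                    fva = (va_eval - V_MIN) * inv_dv
                    ia = int(fva)
                    if ia < 0:
                        ia = 0
                    elif ia > NV - 2:
                        ia = NV - 2
                    fa = fva - ia
                    if fa < 0.0:
                        fa = 0.0
                    elif fa > 1.0:
                        fa = 1.0
                    for gg in range(3):
                        gidx = 10 + gg
                        xi = XINF[i, gidx, ia] * (1.0 - fa) + XINF[i, gidx, ia + 1] * fa
                        q = QE[i, gidx, ia] * (1.0 - fa) + QE[i, gidx, ia + 1] * fa
                        AG[i, s, gg] = xi + (AGOLD[gg] - xi) * q
                    gna_a = GNAA[i] * AG[i, s, 0] * AG[i, s, 0] * AG[i, s, 0] * AG[i, s, 1]
                    gk_a = GKA[i] * AG[i, s, 2] ** 4
                    gl = GPASA[i]
                    gup = gax0 if s == 0 else GAXSEG[i]
                    gdn = GAXSEG[i] if s < ns - 1 else 0.0
                    gt = gna_a + gk_a + gl + gup + gdn
                    geq = (
                        gna_a * ENA[i]
                        + gk_a * EK[i]
                        + gl * EPAS[i]
                        + gup * vprev
                        + (gdn * VA[i, s + 1] if s < ns - 1 else 0.0)
                    )
                    vaeq = geq / gt
                    va_new = vaeq + (va - vaeq) * np.exp(-dt * gt / CSEG[i])
                VA[i, s] = va_new
                vprev = va_new
                if not (-BLOWUP_MV < va_new < BLOWUP_MV):
                    return 1, i, t
            # ---- spike output + feedback scheduling ------------------
            if spiked:
                k = spk_n[0]
                if k < spk_t.shape[0]:
                    spk_t[k] = t + dt
                    spk_i[k] = i
                    spk_n[0] = k + 1
                else:
                    return 2, i, t
                s = n_ext_sources + i
                for jj in range(sy_ptr[s], sy_ptr[s + 1]):
                    u0 = sy_u0[jj]
                    if u0 > 0.0:
                        el = (t + dt) - sy_tlast[jj]
                        r = 1.0 - (1.0 - sy_R[jj]) * np.exp(-el / sy_taurec[jj])
                        rel = u0 * r
                        sy_R[jj] = r * (1.0 - u0)
                        sy_tlast[jj] = t + dt
                    else:
                        rel = 1.0
                    w = sy_g[jj] * rel
                    if w != 0.0:
                        tgt = sy_tgt[jj]
                        dslot = (slot + sy_dstep[jj]) % H
                        m = sy_mix[jj]
                        for kk in range(3):
                            if MIX[m, kk] != 0.0:
                                pending[tgt, dslot, kk] += w * MIX[m, kk]
                    counters[0] += 1
        # ---- recording ----------------------------------------------
        if rec_every > 0 and step % rec_every == 0:
            row = step // rec_every
            for i in range(nn):
                vrec[row, i] = VS[i]
            if rec_axon == 1:
                varec[row] = VA[0, NSEG[0] - 1]
    return 0, -1, 0.0


# --------------------------------------------------------------------------
# python-side wrapper
# --------------------------------------------------------------------------

@dataclass
class _ReceptorConfig:
    ampa: ReceptorKinetics = AMPA_KINETICS
    nmda: ReceptorKinetics = NMDA_KINETICS
    gaba: ReceptorKinetics = GABA_KINETICS
    gaba_e: float = -70.0
    mg_block: bool = False


class CompiledNetwork:
    """A set of TC neurons plus a synapse table, compiled to flat arrays.

    The object carries mutable simulation state; ``advance`` integrates
    forward from the current state.  ``snapshot``/``restore`` support
    reusing a settled resting state across protocol sweeps.
    """

    def __init__(
        self,
        neurons: list[NeuronParams],
        dt: float = 0.1,
        synapses: SynapseTable | None = None,
        nmda_tau_decay: float | None = None,
        gaba_e: float = -70.0,
        mg_block: bool = False,
        rate_factor: float = 1.0,
        receptor_mixes: np.ndarray | None = None,
        max_spike_rate_hz: float = 520.0,
        corrector_passes: int | None = None,
    ):
        if dt <= 0:
            raise ValueError("dt must be > 0")
        self.neurons = list(neurons)
        self.n = len(self.neurons)
        if self.n == 0:
            raise ValueError("need at least one neuron")
        self.dt = float(dt)
        self.rate_factor = float(rate_factor)
        nmda = NMDA_KINETICS if nmda_tau_decay is None else ReceptorKinetics(
            1.0, float(nmda_tau_decay), 0.0
        )
        self.receptors = _ReceptorConfig(nmda=nmda, gaba_e=gaba_e, mg_block=mg_block)
        self.max_spike_rate_hz = max_spike_rate_hz
        self.synapses = synapses if synapses is not None else SynapseTable.empty(0, self.n)
        if receptor_mixes is None:
            receptor_mixes = np.array([[1.0, 0.0, 0.0]])
        self.mixes = np.asarray(receptor_mixes, dtype=float)
        if self.mixes.ndim != 2 or self.mixes.shape[1] != 3:
            raise ValueError("receptor_mixes must be (n_mixes, 3)")
        # midpoint corrector at protocol-grade dt; plain exponential Euler
        # for coarse network steps (validated by statistics convergence)
        if corrector_passes is None:
            corrector_passes = 1 if self.dt <= 0.05 else 0
        self.corrector_passes = int(corrector_passes)
        self._sgold = np.empty(10)
        self._agold = np.empty(3)

        self._build_static()
        self.reset_state()

    # -- construction ----------------------------------------------------
    def _build_static(self) -> None:
        n = self.n
        nseg = np.array(
            [axon_segment_count(p) for p in self.neurons], dtype=np.int64
        )
        self.nseg = nseg
        nsmax = int(nseg.max())
        z = lambda: np.zeros(n)
        (self.CS, self.GPASS, self.EPAS, self.GNA, self.GK, self.GSK, self.GNAP,
         self.GAK, self.GH, self.EH, self.PT, self.PL, self.ENA, self.EK,
         self.CAO, self.QEZ, self.CADA, self.TAUR, self.CAINF, self.INVAREA,
         self.PNCA, self.CSEG, self.GPASA, self.GNAA, self.GKA, self.GAXS0,
         self.GAXSEG) = (z() for _ in range(27))

        self.XINF = np.empty((n, mech.N_GATES, NV))
        self.QE = np.empty((n, mech.N_GATES, NV))
        ga, gb = ghk_factors()
        self.GAV, self.GBV = ga, gb

        f_nmda = 0.0
        # NMDA fraction of the retinal glutamatergic mix, for Ca calibration
        if self.mixes.shape[0] > 0:
            f_nmda = float(self.mixes[0, 1])

        for i, p in enumerate(self.neurons):
            area = np.pi * p.soma_L * p.soma_L * 1e-8  # cm^2
            area_u = area * 1e6
            self.CS[i] = area * CM_UF_CM2 * 1e3  # nF
            self.GPASS[i] = p.pas_g * area_u
            self.EPAS[i] = p.pas_e
            self.GNA[i] = p.gna_max * area_u
            self.GK[i] = p.gk_max * area_u
            self.GSK[i] = p.gsk_max * area_u
            self.GNAP[i] = p.gnap_max * area_u
            self.GAK[i] = p.ga_max * area_u
            self.GH[i] = p.gh_max * area_u
            self.EH[i] = p.e_h
            self.PT[i] = p.t_pcabar * area_u
            self.PL[i] = p.l_pcabar * area_u
            self.ENA[i] = p.ena
            self.EK[i] = p.ek
            self.CAO[i] = p.cao
            self.QEZ[i] = np.exp(-self.dt * self.rate_factor / p.sk_ztau)
            self.CADA[i] = p.ca_gamma * 1e4 / (2.0 * FARADAY * CA_BUFFER_DEPTH_UM)
            self.TAUR[i] = p.ca_taur
            self.CAINF[i] = CA_RESTING_MM
            self.INVAREA[i] = 1e-6 / area
            self.PNCA[i] = nmda_ca_permeability(1.0, p.cao) if f_nmda > 0 else 0.0

            lseg = p.axon_L / nseg[i]
            aseg = np.pi * p.axon_diam * lseg * 1e-8
            aseg_u = aseg * 1e6
            self.CSEG[i] = aseg * CM_UF_CM2 * 1e3
            self.GPASA[i] = p.pas_g * aseg_u
            self.GNAA[i] = p.axon_gna_max * aseg_u
            self.GKA[i] = p.axon_gk_max * aseg_u
            # axial resistances (MOhm); conductance in uS = 1/MOhm
            r_half_soma = 0.01 * p.ra * (p.soma_L / 2.0) / (
                np.pi * (p.soma_L / 2.0) ** 2
            )
            r_half_seg = 0.01 * p.ra * (lseg / 2.0) / (
                np.pi * (p.axon_diam / 2.0) ** 2
            )
            self.GAXS0[i] = 1.0 / (r_half_soma + r_half_seg)
            self.GAXSEG[i] = 1.0 / (2.0 * r_half_seg)

            xinf, qe = build_gate_tables(p, self.dt, self.rate_factor)
            self.XINF[i] = xinf
            self.QE[i] = qe

        self.nsmax = nsmax
        self._prepare_receptors()
        self._prepare_synapses()

    def _prepare_receptors(self) -> None:
        r = self.receptors
        kins = (r.ampa, r.nmda, r.gaba)
        self.QD = np.array([np.exp(-self.dt / k.tau_decay) for k in kins])
        self.QR = np.array([np.exp(-self.dt / k.tau_rise) for k in kins])
        self.NORM = np.array([k.norm for k in kins])
        self.EGABA = float(r.gaba_e)

    def _prepare_synapses(self) -> None:
        t = self.synapses
        self.sy_dstep = np.maximum(
            np.round(t.delay_ms / self.dt).astype(np.int64), 1
        )
        max_delay = int(self.sy_dstep.max()) if t.n_synapses else 1
        self.H = max_delay + 2
        self.pending = np.zeros((self.n, self.H, 3))

    # -- state -----------------------------------------------------------
    def reset_state(self, v0: float = -70.0) -> None:
        n = self.n
        self.VS = np.full(n, v0)
        self.SG = np.empty((n, 10))
        self.AG = np.empty((n, self.nsmax, 3))
        iv = int((v0 - V_MIN) / DV)
        for i in range(n):
            for g in range(10):
                self.SG[i, g] = self.XINF[i, g, iv]
            for g in range(3):
                self.AG[i, :, g] = self.XINF[i, 10 + g, iv]
        self.ZSK = np.full(n, mech.sk_zinf(CA_RESTING_MM))
        self.CAI = np.full(n, CA_RESTING_MM)
        self.VA = np.full((n, self.nsmax), v0)
        self.SA = np.zeros((n, 3))
        self.SB = np.zeros((n, 3))
        self.pending[:] = 0.0
        self.last_spike = np.full(n, -1e9)
        self.t_ms = 0.0
        self.abs_step = 0
        t = self.synapses
        self.sy_R = np.ones(t.n_synapses)
        self.sy_tlast = np.full(t.n_synapses, -1e9)
        self.n_events_scheduled = 0

    def snapshot(self) -> dict:
        keys = ("VS", "SG", "AG", "ZSK", "CAI", "VA", "SA", "SB", "pending",
                "last_spike", "sy_R", "sy_tlast")
        s = {k: getattr(self, k).copy() for k in keys}
        s["t_ms"] = self.t_ms
        s["abs_step"] = self.abs_step
        return s

    def restore(self, snap: dict) -> None:
        for k, v in snap.items():
            if isinstance(v, np.ndarray):
                getattr(self, k)[...] = v
            else:
                setattr(self, k, v)

    # -- running ---------------------------------------------------------
    def advance(
        self,
        duration_ms: float,
        i_inj_nA: np.ndarray | float = 0.0,
        stimulus_events: tuple[np.ndarray, np.ndarray] | None = None,
        record_every: int = 0,
        record_axon: bool = False,
    ) -> dict:
        """Integrate ``duration_ms`` forward from the current state.

        ``stimulus_events`` is ``(times_ms, source_ids)`` of external source
        spikes with times relative to the global time origin (they must not
        precede the current time).  Returns spikes (absolute ms) and any
        recorded voltages.
        """
        n_steps = int(round(duration_ms / self.dt))
        iinj = np.broadcast_to(np.asarray(i_inj_nA, dtype=float), (self.n,)).copy()
        if stimulus_events is not None:
            ev_t, ev_s = stimulus_events
            ev_t = np.asarray(ev_t, dtype=float)
            ev_s = np.asarray(ev_s, dtype=np.int64)
            order = np.argsort(ev_t, kind="stable")
            ev_step = np.round(ev_t[order] / self.dt).astype(np.int64)
            ev_src = ev_s[order]
            keep = ev_step >= self.abs_step
            ev_step, ev_src = ev_step[keep], ev_src[keep]
        else:
            ev_step = np.zeros(0, dtype=np.int64)
            ev_src = np.zeros(0, dtype=np.int64)
        ev_cursor = np.zeros(1, dtype=np.int64)

        cap = max(int(self.max_spike_rate_hz * duration_ms / 1e3 * self.n), 1024)
        spk_t = np.empty(cap)
        spk_i = np.empty(cap, dtype=np.int64)
        spk_n = np.zeros(1, dtype=np.int64)
        if record_every > 0:
            nrec = (n_steps + record_every - 1) // record_every
            vrec = np.empty((nrec, self.n))
            varec = np.empty(nrec) if record_axon else np.empty(1)
        else:
            vrec = np.empty((1, self.n))
            varec = np.empty(1)
        counters = np.zeros(2, dtype=np.int64)

        t = self.synapses
        err, err_i, err_t = _advance_kernel(
            n_steps, self.dt, self.t_ms,
            self.VS, self.SG, self.ZSK, self.CAI, self.VA, self.AG,
            self.nseg, self.last_spike,
            self.XINF, self.QE, self.GAV, self.GBV,
            self.CS, self.GPASS, self.EPAS, self.GNA, self.GK, self.GSK,
            self.GNAP, self.GAK, self.GH, self.EH, self.PT, self.PL,
            self.ENA, self.EK, self.CAO, self.QEZ, self.CADA, self.TAUR,
            self.CAINF, self.INVAREA, self.PNCA,
            self.CSEG, self.GPASA, self.GNAA, self.GKA, self.GAXS0, self.GAXSEG,
            self.SA, self.SB, self.QD, self.QR, self.NORM, self.EGABA,
            self.mixes, 1 if self.receptors.mg_block else 0,
            self.pending, self.H, self.abs_step,
            ev_step, ev_src, ev_cursor,
            t.src_ptr, t.target, t.g, t.mix_id, self.sy_dstep,
            self.sy_R, self.sy_tlast, t.u0, t.tau_rec,
            t.n_sources,
            iinj,
            spk_t, spk_i, spk_n, vrec, record_every, varec,
            1 if record_axon else 0,
            counters, self.corrector_passes, self._sgold, self._agold,
        )
        if err == 1:
            raise IntegrationError(err_i, err_t)
        if err == 2:
            raise IntegrationError(err_i, err_t)
        self.t_ms += n_steps * self.dt
        self.abs_step += n_steps
        self.n_events_scheduled += int(counters[0])
        k = int(spk_n[0])
        out = {
            "spike_times_ms": spk_t[:k].copy(),
            "spike_units": spk_i[:k].copy(),
        }
        if record_every > 0:
            out["v_soma"] = vrec
            out["t_rec_ms"] = (
                self.t_ms - n_steps * self.dt
                + np.arange(vrec.shape[0]) * record_every * self.dt
            )
            if record_axon:
                out["v_axon_distal"] = varec
        return out

    def settle(self, duration_ms: float = 1000.0) -> None:
        """Advance with no input to reach a free steady state."""
        self.advance(duration_ms)
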