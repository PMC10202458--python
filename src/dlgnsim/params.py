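"""Tunable description of a two-compartment thalamocortical (TC) neuron.

The model is a "pen-and-ball" neuron: a single-segment somatodendritic
cylinder carrying nine membrane mechanisms plus calcium dynamics, and a
multisegment axonal cable carrying leak, fast Na+ and delayed-rectifier K+.
Exactly 29 quantities are open for fitting; each is addressed by the flat
key string used in serialized parameter tables (e.g.
``soma(0.5).TC_iT_Des98.pcabar``).

Scales: parameters whose plausible range spans many orders of magnitude
(conductance densities, permeabilities, the Ca-buffer fraction) are searched
and jittered in log10 space; the rest are linear.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, fields, replace
from typing import Iterator

__all__ = [
    "NeuronParams",
    "PARAM_TABLE",
    "PARAM_KEYS",
    "N_PARAMS",
    "ParameterError",
    "midpoint_params",
    "canonical_params",
]


class ParameterError(ValueError):
    """A parameter violates its bounds or a structural invariant."""


# field name -> (flat key, scale, lo, hi)
# hi/lo are the open-parameter bounds; reversal-potential bounds are stored
# low-to-high even where the source table prints them in the other order.
PARAM_TABLE: dict[str, tuple[str, str, float, float]] = {
    "soma_L": ("soma.L", "linear", 20.0, 200.0),
    "pas_e": ("soma(0.5).pas.e", "linear", -90.0, -55.0),
    "pas_g": ("soma(0.5).pas.g", "log", 1e-7, 1e-1),
    "gk_max": ("soma(0.5).TC_HH.gk_max", "log", 1e-7, 1e-1),
    "gna_max": ("soma(0.5).TC_HH.gna_max", "log", 1e-7, 1e-1),
    "vtraub": ("soma(0.5).TC_HH.vtraub", "linear", -70.0, 20.0),
    "vtraub2": ("soma(0.5).TC_HH.vtraub2", "linear", -70.0, 20.0),
    "gsk_max": ("soma(0.5).SK_E2.gSK_E2bar", "log", 1e-7, 1e-1),
    "sk_ztau": ("soma(0.5).SK_E2.zTau", "linear", 1.0, 500.0),
    "t_shift": ("soma(0.5).TC_iT_Des98.shift", "linear", -25.0, 25.0),
    "t_actshift": ("soma(0.5).TC_iT_Des98.actshift", "linear", -25.0, 25.0),
    "t_pcabar": ("soma(0.5).TC_iT_Des98.pcabar", "log", 1e-7, 5e-1),
    "gh_max": ("soma(0.5).TC_ih_Bud97.gh_max", "log", 1e-7, 5e-1),
    "e_h": ("soma(0.5).TC_ih_Bud97.e_h", "linear", -50.0, 0.0),
    "gnap_max": ("soma(0.5).TC_Nap_Et2.gNap_Et2bar", "log", 1e-7, 5e-1),
    "ca_taur": ("soma(0.5).TC_cad.taur", "linear", 2.0, 30.0),
    "ca_gamma": ("soma(0.5).TC_cad.gamma", "log", 1e-5, 1e-1),
    "ga_max": ("soma(0.5).TC_iA.gk_max", "log", 1e-7, 1e-1),
    "l_pcabar": ("soma(0.5).TC_iL.pcabar", "log", 1e-7, 1e-1),
    "cao": ("soma.cao", "linear", 1.0, 6.0),
    "ena": ("soma.ena, axon.ena", "linear", 40.0, 65.0),
    "ek": ("soma.ek, axon.ek", "linear", -110.0, -65.0),
    "axon_diam": ("axon.diam", "linear", 0.5, 5.0),
    "axon_L": ("axon.L", "linear", 100.0, 1000.0),
    "axon_gk_max": ("axon(0.5).TC_HH.gk_max", "log", 1e-7, 1.0),
    "axon_gna_max": ("axon(0.5).TC_HH.gna_max", "log", 1e-7, 1.0),
    "axon_vtraub": ("axon(0.5).TC_HH.vtraub", "linear", -70.0, 20.0),
    "axon_vtraub2": ("axon(0.5).TC_HH.vtraub2", "linear", -70.0, 20.0),
    "ra": ("axon.Ra, soma.Ra", "linear", 20.0, 120.0),
}

PARAM_KEYS = tuple(key for key, _, _, _ in PARAM_TABLE.values())
N_PARAMS = len(PARAM_TABLE)  # 29

# depth of the submembrane Ca shell (um); not a free parameter
CA_BUFFER_DEPTH_UM = 0.1


@dataclass(frozen=True)
class NeuronParams:
    """The 29 tunable quantities of the TC neuron model.

    Units: lengths um; conductance densities S/cm^2; permeabilities cm/s;
    potentials mV; time constants ms; cao mM; Ra ohm*cm; gamma is the
    dimensionless fraction of Ca influx reaching the free pool.
    """

    soma_L: float
    pas_e: float
    pas_g: float
    gk_max: float
    gna_max: float
    vtraub: float
    vtraub2: float
    gsk_max: float
    sk_ztau: float
    t_shift: float
    t_actshift: float
    t_pcabar: float
    gh_max: float
    e_h: float
    gnap_max: float
    ca_taur: float
    ca_gamma: float
    ga_max: float
    l_pcabar: float
    cao: float
    ena: float
    ek: float
    axon_diam: float
    axon_L: float
    axon_gk_max: float
    axon_gna_max: float
    axon_vtraub: float
    axon_vtraub2: float
    ra: float

    def __post_init__(self) -> None:
        for f in fields(self):
            _, _, lo, hi = PARAM_TABLE[f.name]
            v = getattr(self, f.name)
            if not math.isfinite(v):
                raise ParameterError(f"{f.name} is not finite")
            if not (lo <= v <= hi):
                raise ParameterError(
                    f"{f.name}={v!r} outside bounds [{lo}, {hi}]"
                )
        if self.axon_L <= self.axon_diam:
            raise ParameterError("axon length must exceed axon diameter")
        if self.axon_diam >= self.soma_L:
            raise ParameterError("axon diameter must be smaller than soma diameter")

    # -- structural checks shared with post-hoc model validation ---------
    def structural_checks(self) -> dict[str, bool]:
        return {
            "axon_longer_than_wide": self.axon_L > self.axon_diam,
            "axon_thinner_than_soma": self.axon_diam < self.soma_L,
            "ca_buffer_shallower_than_soma": CA_BUFFER_DEPTH_UM < self.soma_L / 2.0,
        }

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict[str, float]:
        """Flat key -> value table using the canonical key strings."""
        return {
            PARAM_TABLE[f.name][0]: getattr(self, f.name) for f in fields(self)
        }

    @classmethod
    def from_dict(cls, table: dict[str, float]) -> "NeuronParams":
        key_to_field = {key: name for name, (key, _, _, _) in PARAM_TABLE.items()}
        kwargs: dict[str, float] = {}
        for key, value in table.items():
            if key not in key_to_field:
                raise ParameterError(f"unknown parameter key {key!r}")
            kwargs[key_to_field[key]] = float(value)
        missing = set(key_to_field.values()) - set(kwargs)
        if missing:
            raise ParameterError(f"missing parameters: {sorted(missing)}")
        return cls(**kwargs)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "NeuronParams":
        return cls.from_dict(json.loads(text))

    def replace(self, **changes: float) -> "NeuronParams":
        return replace(self, **changes)

    def __iter__(self) -> Iterator[float]:
        return (getattr(self, f.name) for f in fields(self))


def midpoint_params() -> NeuronParams:
    """Parameter set at the midpoint of every bound (log-midpoint where the
    search scale is logarithmic).  Structurally valid but not tuned."""
    kwargs = {}
    for name, (_, scale, lo, hi) in PARAM_TABLE.items():
        if scale == "log":
            kwargs[name] = math.sqrt(lo * hi)
        else:
            kwargs[name] = 0.5 * (lo + hi)
    return NeuronParams(**kwargs)


def canonical_params() -> NeuronParams:
    """Reference P7-P10 TC parameter set used to seed heterogeneous
    populations.

    Hand-tuned to rest near -70 mV, fire tonically on depolarizing steps,
    produce T-current rebound bursts after hyperpolarization, and propagate
    spikes without decrement along the axon.
    """
    return NeuronParams(
        soma_L=60.0,
        pas_e=-72.0,
        pas_g=5.0e-5,
        gk_max=1.0e-2,
        gna_max=4.0e-2,
        vtraub=-63.0,
        vtraub2=-63.0,
        gsk_max=3.0e-4,
        sk_ztau=80.0,
        t_shift=0.0,
        t_actshift=0.0,
        t_pcabar=9.0e-5,
        gh_max=1.2e-5,
        e_h=-43.0,
        gnap_max=6.0e-6,
        ca_taur=10.0,
        ca_gamma=1.0e-2,
        ga_max=2.0e-3,
        l_pcabar=1.0e-5,
        cao=2.0,
        ena=50.0,
        ek=-90.0,
        axon_diam=1.5,
        axon_L=150.0,
        axon_gk_max=8.0e-2,
        axon_gna_max=3.0e-1,
        axon_vtraub=-63.0,
        axon_vtraub2=-63.0,
        ra=100.0,
    )
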