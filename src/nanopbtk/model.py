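"""State vector and ODE right-hand side of the nanoparticle PBTK model.

The body is described by 23 mass states (ng): three respiratory surface
pools (upper airway, tracheobronchial, alveolar) plus the alveolar
phagocytic-cell pool; the lung exchange block (capillary blood,
interstitial tissue, interstitial phagocytic cells); arterial and venous
blood; capillary/tissue/phagocytic-cell triplets for liver, kidney, spleen
and rest-of-body; and two excretion sinks (feces, urine).

Each systemic organ is permeability-limited: capillary blood exchanges with
tissue through a term X_o * Q_o * (C_cab - C_tis / P_o), and tissue
exchanges with resident phagocytic cells through a time-dependent Hill
uptake rate K_up(t) = K_max * t^n / (K_50^n + t^n) opposed by first-order
release K_out.  The Hill clock is absolute simulation time from exposure
onset, shared by all organs.  Organs are perfused in parallel; the lung
capillary sits in series between venous and arterial blood and receives the
whole cardiac output.

Because K_up depends on time rather than on mass, the full system is linear
in the state: trajectories scale exactly with the deposited dose.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .parameters import ParameterSet, SYSTEMIC_ORGANS

__all__ = [
    "STATE_NAMES",
    "STATE_INDEX",
    "ExposureScenario",
    "hill_uptake_rate",
    "organ_fluxes",
    "respiratory_fluxes",
    "rhs",
    "mass_balance_audit",
]

_ORGAN_KEY = {"liver": "li", "kidney": "ki", "spleen": "spl", "rob": "rob"}

STATE_NAMES: tuple[str, ...] = (
    "M_upp", "M_tra", "M_alv", "M_alv_PCs",
    "M_lu_cab", "M_lu_tis", "M_lu_PCs",
    "M_art", "M_ven",
    "M_li_cab", "M_li_tis", "M_li_PCs",
    "M_ki_cab", "M_ki_tis", "M_ki_PCs",
    "M_spl_cab", "M_spl_tis", "M_spl_PCs",
    "M_rob_cab", "M_rob_tis", "M_rob_PCs",
    "M_feces", "M_urine",
)
STATE_INDEX: dict[str, int] = {name: i for i, name in enumerate(STATE_NAMES)}
N_STATES = len(STATE_NAMES)


@dataclass(frozen=True)
class ExposureScenario:
    """Inhalation dosing: instantaneous regional deposits or a constant source.

    ``bolus`` mode places ``deposits`` (ng, keyed upp/tra/alv) in the
    respiratory surface pools at t = 0.  ``continuous`` mode feeds the same
    pools at rate EC * BR * FR_region while t < duration, with the aerosol
    concentration EC in ng/L, the breathing rate BR in L/min (converted to
    L/h internally), and regional deposition fractions FR_*.
    """

    mode: str = "bolus"
    deposits: Mapping[str, float] = field(default_factory=dict)  # ng
    EC: float = 0.0        # ng/L
    BR: float = 0.0        # L/min
    duration: float = 0.0  # h
    FR_upp: float = 0.0
    FR_tra: float = 0.0
    FR_alv: float = 0.0

    def __post_init__(self):
        if self.mode not in ("bolus", "continuous"):
            raise ValueError(f"unknown exposure mode {self.mode!r}")
        for region, mass in self.deposits.items():
            if region not in ("upp", "tra", "alv"):
                raise ValueError(f"unknown deposit region {region!r}")
            if mass < 0:
                raise ValueError(f"negative deposit in {region!r}")
        if min(self.EC, self.BR, self.duration) < 0:
            raise ValueError("EC, BR and duration must be non-negative")
        fr = (self.FR_upp, self.FR_tra, self.FR_alv)
        if min(fr) < 0 or sum(fr) > 1 + 1e-9:
            raise ValueError("deposition fractions must be in [0, 1] and sum to <= 1")

    def initial_state(self) -> np.ndarray:
        y0 = np.zeros(N_STATES)
        if self.mode == "bolus":
            for region, mass in self.deposits.items():
                y0[STATE_INDEX[f"M_{region}"]] = mass
        return y0

    def inhalation_rate(self, t: float) -> float:
        """Raw inhaled aerosol mass rate EC * BR at time t, ng/h (before
        applying regional deposition fractions)."""
        if self.mode == "continuous" and t < self.duration:
            return self.EC * self.BR * 60.0
        return 0.0

    def source_rate(self, t: float) -> float:
        """Total deposited mass rate at time t, ng/h (the non-deposited
        fraction is exhaled and never enters the model)."""
        return self.inhalation_rate(t) * (self.FR_upp + self.FR_tra + self.FR_alv)

    def delivered(self, t: float) -> float:
        """Cumulative externally delivered mass by time t, ng (incl. bolus)."""
        total = sum(self.deposits.values()) if self.mode == "bolus" else 0.0
        if self.mode == "continuous":
            total += (self.EC * self.BR * 60.0
                      * (self.FR_upp + self.FR_tra + self.FR_alv)
                      * min(t, self.duration))
        return total

    def fingerprint(self) -> str:
        import hashlib
        import json
        payload = json.dumps(
            {"mode": self.mode, "deposits": dict(self.deposits), "EC": self.EC,
             "BR": self.BR, "duration": self.duration,
             "FR": [self.FR_upp, self.FR_tra, self.FR_alv]},
            sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def hill_uptake_rate(K_max: float, K_50: float, n0: float, t):
    """Time-dependent phagocytic uptake rate K_max * t^n0 / (K_50^n0 + t^n0), 1/h.

    Zero at t = 0, half-maximal at t = K_50, saturating at K_max.  Accepts
    scalar or array times; negative times are a domain error.
    """
    if K_50 <= 0 or n0 <= 0:
        raise ValueError("K_50 and n0 must be strictly positive")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("the uptake clock t must be non-negative")
    tn = np.power(t, n0)
    out = K_max * tn / (K_50 ** n0 + tn)
    return float(out) if out.ndim == 0 else out


def organ_fluxes(organ: str, state: np.ndarray, params: ParameterSet,
                 t: float) -> dict[str, float]:
    """Net rates (ng/h) for the capillary/tissue/PC triplet of one systemic organ.

    Capillary: arterial wash-through minus permeability-limited exchange.
    Tissue: that exchange, minus Hill uptake into phagocytic cells plus
    release, minus urinary excretion (kidney) plus upper-airway inflow (rob).
    PCs: Hill uptake minus release, minus biliary excretion (liver).
    """
    if organ not in SYSTEMIC_ORGANS:
        raise ValueError(f"unknown systemic organ {organ!r}")
    key = _ORGAN_KEY[organ]
    phys = params.physiological
    op = phys.organs[organ]
    oc = params.chemical[organ]

    M_art = state[STATE_INDEX["M_art"]]
    M_cab = state[STATE_INDEX[f"M_{key}_cab"]]
    M_tis = state[STATE_INDEX[f"M_{key}_tis"]]
    M_pcs = state[STATE_INDEX[f"M_{key}_PCs"]]

    wash = op.Q * (M_art / phys.V_art - M_cab / op.V_cab)
    exchange = oc.X * op.Q * (M_cab / op.V_cab - M_tis / (oc.P * op.V_tis))
    k_up = hill_uptake_rate(oc.K_max, oc.K_50, oc.n0, t)
    phago = k_up * M_tis - oc.K_out * M_pcs

    d_cab = wash - exchange
    d_tis = exchange - phago
    d_pcs = phago
    if organ == "kidney":
        d_tis -= oc.K_excrete * M_tis
    elif organ == "rob":
        d_tis += params.respiratory.K_upp_robtis * state[STATE_INDEX["M_upp"]]
    if organ == "liver":
        d_pcs -= oc.K_excrete * M_pcs
    return {"cab": d_cab, "tis": d_tis, "PCs": d_pcs}


def respiratory_fluxes(state: np.ndarray, params: ParameterSet,
                       scenario: ExposureScenario, t: float) -> dict[str, float]:
    """Net rates (ng/h) for the respiratory-tract and lung exchange states.

    The alveolar phagocytic pool is cleared up the mucociliary escalator into
    the tracheobronchial pool (a gain there), and the tracheobronchial pool
    drains to feces.  The alveolar surface exchanges with the lung
    interstitium, which in turn exchanges with lung capillary blood through
    the permeability-limited term and with interstitial phagocytic cells
    through its own Hill uptake.
    """
    phys = params.physiological
    resp = params.respiratory
    lung = phys.organs["lung"]
    source = scenario.inhalation_rate(t)

    M_upp = state[STATE_INDEX["M_upp"]]
    M_tra = state[STATE_INDEX["M_tra"]]
    M_alv = state[STATE_INDEX["M_alv"]]
    M_apcs = state[STATE_INDEX["M_alv_PCs"]]
    M_lucab = state[STATE_INDEX["M_lu_cab"]]
    M_lutis = state[STATE_INDEX["M_lu_tis"]]
    M_lupcs = state[STATE_INDEX["M_lu_PCs"]]
    M_ven = state[STATE_INDEX["M_ven"]]

    k_alv_up = hill_uptake_rate(resp.K_alvmax, resp.K_alv50, resp.n0_alv, t)
    k_int_up = hill_uptake_rate(resp.K_inter_max, resp.K_inter50, resp.n0_inter, t)

    alv_phago = k_alv_up * M_alv - resp.K_alvout * M_apcs
    inter_phago = k_int_up * M_lutis - resp.K_interout * M_lupcs
    alv_inter = resp.K_alv_inter * M_alv - resp.K_inter_alv * M_lutis
    lung_exchange = resp.X_lu * lung.Q * (
        M_lucab / lung.V_cab - M_lutis / (resp.P_lu * lung.V_tis))

    return {
        "upp": source * scenario.FR_upp
        - (resp.K_upp_robtis + resp.K_upp_feces) * M_upp,
        "tra": source * scenario.FR_tra
        + resp.K_alvpcs_trach * M_apcs - resp.K_trach_feces * M_tra,
        "alv": source * scenario.FR_alv - alv_inter - alv_phago,
        "alv_PCs": alv_phago - resp.K_alvpcs_trach * M_apcs,
        "lu_tis": alv_inter + lung_exchange - inter_phago,
        "lu_PCs": inter_phago,
        "lu_cab": phys.QC * (M_ven / phys.V_ven - M_lucab / lung.V_cab)
        - lung_exchange,
    }


def rhs(t: float, state: np.ndarray, params: ParameterSet,
        scenario: ExposureScenario) -> np.ndarray:
    """Full state derivative (ng/h): organ and respiratory fluxes plus
    circulation closure and excretion sinks.

    Venous blood collects every systemic capillary outflow; arterial blood is
    fed by the lung capillary.  The sum of all 23 components equals the
    instantaneous external source exactly (internal transfers cancel).
    """
    state = np.asarray(state, dtype=float)
    if not np.all(np.isfinite(state)):
        raise ValueError("non-finite state passed to rhs")
    phys = params.physiological
    d = np.zeros(N_STATES)

    resp_rates = respiratory_fluxes(state, params, scenario, t)
    for name, rate in resp_rates.items():
        d[STATE_INDEX[f"M_{name}"]] = rate

    venous_in = 0.0
    for organ in SYSTEMIC_ORGANS:
        key = _ORGAN_KEY[organ]
        rates = organ_fluxes(organ, state, params, t)
        d[STATE_INDEX[f"M_{key}_cab"]] = rates["cab"]
        d[STATE_INDEX[f"M_{key}_tis"]] = rates["tis"]
        d[STATE_INDEX[f"M_{key}_PCs"]] = rates["PCs"]
        op = phys.organs[organ]
        venous_in += op.Q * state[STATE_INDEX[f"M_{key}_cab"]] / op.V_cab

    M_lucab = state[STATE_INDEX["M_lu_cab"]]
    M_art = state[STATE_INDEX["M_art"]]
    M_ven = state[STATE_INDEX["M_ven"]]
    lung = phys.organs["lung"]
    d[STATE_INDEX["M_art"]] = phys.QC * (M_lucab / lung.V_cab - M_art / phys.V_art)
    d[STATE_INDEX["M_ven"]] = venous_in - phys.QC * M_ven / phys.V_ven

    resp = params.respiratory
    d[STATE_INDEX["M_feces"]] = (
        resp.K_upp_feces * state[STATE_INDEX["M_upp"]]
        + resp.K_trach_feces * state[STATE_INDEX["M_tra"]]
        + params.chemical["liver"].K_excrete * state[STATE_INDEX["M_li_PCs"]]
    )
    d[STATE_INDEX["M_urine"]] = (
        params.chemical["kidney"].K_excrete * state[STATE_INDEX["M_ki_tis"]]
    )
    return d


def mass_balance_audit(result, scenario: ExposureScenario) -> float:
    """Maximum |total body burden + sinks - delivered dose| over the grid, ng.

    A solver-quality gate: the flux table conserves mass exactly, so any
    residual is integration error.
    """
    totals = result.states.sum(axis=0)
    delivered = np.array([scenario.delivered(t) for t in result.times])
    baseline = totals[0] - delivered[0]
    return float(np.max(np.abs(totals - baseline - delivered)))
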