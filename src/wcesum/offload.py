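"""Time and energy cost models for local vs cloud execution of summarization.

Three strategies are compared for a summarization workload:

* local: the whole summary is computed on the smartphone and only the
  keyframes (volume V_K) are uploaded;
* full offloading: the complete video (V_F) is uploaded and summarized in the
  cloud;
* adaptive offloading: redundancy removal runs locally and only the
  non-redundant segments (V_S) are uploaded for classification in the cloud.

Time is compute time plus transmission time (volume / bandwidth) plus a
miscellaneous constant; energy weights the compute term by the active or idle
power draw and the transmission term by the radio power.  Units are fixed at
the interface: volumes in bits, bandwidth in bits/s, powers in W, energies
in J.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CostParameters",
    "CostReport",
    "EnergyLedger",
    "time_costs",
    "energy_costs",
    "choose_strategy",
    "ledger_totals",
]

STRATEGIES = ("local", "full", "adaptive")


@dataclass
class CostParameters:
    """Simulation-testbed parameters of the offloading cost models.

    t_fl / t_fc : full-summary compute time on the local server / cloud (s).
    t_pc : classification time for the pre-processed frames on the cloud (s).
    v_k, v_f, v_s : data volumes of keyframes, full video and non-redundant
        segments (bits), with v_k <= v_s <= v_f.
    bw : available bandwidth (bits/s).
    k_misc : miscellaneous time (receiving frames, resource monitoring; s).
    ec_c, ec_t, ec_i : smartphone power draw while computing, transmitting
        and idle (W).
    t_rl : optional redundancy-only local compute time (s), used by the
        corrected adaptive energy mode.
    """

    t_fl: float
    t_fc: float
    t_pc: float
    v_k: float
    v_f: float
    v_s: float
    bw: float
    k_misc: float = 0.0
    ec_c: float = 0.0
    ec_t: float = 0.0
    ec_i: float = 0.0
    t_rl: float | None = None

    def __post_init__(self) -> None:
        for name in ("t_fl", "t_fc", "t_pc", "v_k", "v_f", "v_s", "k_misc", "ec_c", "ec_t", "ec_i"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.bw <= 0:
            raise ValueError("bandwidth must be positive")
        if not (self.v_k <= self.v_s <= self.v_f):
            raise ValueError("volumes must satisfy v_k <= v_s <= v_f")


@dataclass
class CostReport:
    """Computed strategy costs plus argmin picks and the adaptive-wins flags."""

    p_local: float
    p_full: float
    p_adaptive: float
    e_local: float
    e_full: float
    e_adaptive: float
    best_time: str = ""
    best_energy: str = ""
    inequality_holds_time: bool = False
    inequality_holds_energy: bool = False

    def __post_init__(self) -> None:
        times = {"local": self.p_local, "full": self.p_full, "adaptive": self.p_adaptive}
        energies = {"local": self.e_local, "full": self.e_full, "adaptive": self.e_adaptive}
        self.best_time = min(times, key=times.get)
        self.best_energy = min(energies, key=energies.get)
        self.inequality_holds_time = self.p_adaptive < self.p_local and self.p_adaptive < self.p_full
        self.inequality_holds_energy = self.e_adaptive < self.e_local and self.e_adaptive < self.e_full


def time_costs(p: CostParameters) -> tuple[float, float, float]:
    """Execution times (P_local, P_full, P_adaptive) in seconds.

    P_local = T_FL + V_K/BW + K; P_full = T_FC + V_F/BW + K;
    P_adaptive = T_PC + V_S/BW + K.
    """
    p_l = p.t_fl + p.v_k / p.bw + p.k_misc
    p_f = p.t_fc + p.v_f / p.bw + p.k_misc
    p_a = p.t_pc + p.v_s / p.bw + p.k_misc
    return p_l, p_f, p_a


def energy_costs(p: CostParameters, adaptive_mode: str = "as_printed") -> tuple[float, float, float]:
    """Smartphone energies (E_local, E_full, E_adaptive) in joules.

    E_local = T_FL*EC_C + (V_K/BW + K)*EC_T;
    E_full  = T_FC*EC_I + (V_F/BW + K)*EC_T;
    E_adaptive = T_FL*EC_C + (V_S/BW + K)*EC_T in the default ``as_printed``
    mode.  The adaptive strategy computes only redundancy locally, so the
    ``corrected`` mode substitutes the redundancy-only time T_RL for T_FL in
    the first term (requires ``t_rl``).
    """
    e_l = p.t_fl * p.ec_c + (p.v_k / p.bw + p.k_misc) * p.ec_t
    e_f = p.t_fc * p.ec_i + (p.v_f / p.bw + p.k_misc) * p.ec_t
    if adaptive_mode == "as_printed":
        t_local = p.t_fl
    elif adaptive_mode == "corrected":
        if p.t_rl is None:
            raise ValueError("corrected mode requires t_rl")
        t_local = p.t_rl
    else:
        raise ValueError(f"unknown adaptive_mode: {adaptive_mode!r}")
    e_a = t_local * p.ec_c + (p.v_s / p.bw + p.k_misc) * p.ec_t
    return e_l, e_f, e_a


def choose_strategy(
    p: CostParameters, objective: str = "energy", adaptive_mode: str = "as_printed"
) -> tuple[str, CostReport]:
    """Pick the cheapest strategy for the given objective and report all costs."""
    if objective not in ("time", "energy"):
        raise ValueError(f"unknown objective: {objective!r}")
    p_l, p_f, p_a = time_costs(p)
    e_l, e_f, e_a = energy_costs(p, adaptive_mode=adaptive_mode)
    report = CostReport(p_local=p_l, p_full=p_f, p_adaptive=p_a, e_local=e_l, e_full=e_f, e_adaptive=e_a)
    return (report.best_time if objective == "time" else report.best_energy), report


@dataclass
class EnergyLedger:
    """Per-component energy ledger: (component, strategy, tier) -> joules.

    Strategies are 'local', 'full', 'adaptive'; tiers are 'smartphone' and
    'cloud'.  Missing cells are simply absent and contribute zero.
    """

    rows: list = field(default_factory=list)  # (component, strategy, tier, joules)

    def add(self, component: str, strategy: str, tier: str, joules: float) -> "EnergyLedger":
        if joules < 0:
            raise ValueError("negative cell")
        if strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy: {strategy!r}")
        if tier not in ("smartphone", "cloud"):
            raise ValueError(f"unknown tier: {tier!r}")
        self.rows.append((component, strategy, tier, float(joules)))
        return self

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["component", "strategy", "tier", "joules"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "EnergyLedger":
        ledger = cls()
        for _, r in df.iterrows():
            ledger.add(r["component"], r["strategy"], r["tier"], r["joules"])
        return ledger


def ledger_totals(ledger: EnergyLedger, printed_totals: dict | None = None) -> dict:
    """Smartphone subtotal and grand total per strategy, from the ledger cells.

    If ``printed_totals`` maps strategies to externally reported grand totals,
    each computed total is checked against it and any disagreement beyond
    0.5 J is flagged in ``mismatches`` rather than overwritten — published
    tables occasionally fail their own arithmetic.
    """
    if not ledger.rows:
        raise ValueError("empty ledger")
    if any(r[3] < 0 for r in ledger.rows):
        raise ValueError("negative cell")
    result: dict = {}
    for strat in STRATEGIES:
        phone = sum(r[3] for r in ledger.rows if r[1] == strat and r[2] == "smartphone")
        cloud = sum(r[3] for r in ledger.rows if r[1] == strat and r[2] == "cloud")
        result[strat] = {
            "smartphone_total": phone,
            "cloud_total": cloud,
            "grand_total": phone + cloud,
        }
    mismatches = {}
    if printed_totals:
        for strat, printed in printed_totals.items():
            computed = result[strat]["grand_total"]
            if abs(computed - printed) > 0.5:
                mismatches[strat] = {"computed": computed, "printed": printed}
    result["mismatches"] = mismatches
    return result
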