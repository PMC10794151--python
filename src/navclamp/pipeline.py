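"""Per-cell orchestration: preprocess, isolate, fit, derive densities.

`analyze_cell` consumes a dict of condition-labelled sweep families from
one cell and produces a JSON-serializable record with peak currents,
percent inhibition per drug, Boltzmann activation parameters, the kinetics
table, density estimates and the responder flag.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from . import activation, density, isolation, kinetics
from .calibrate import default_params
from .model import ValidationError
from .preprocess import preprocess_family
from .traces import SweepFamily

__all__ = ["AnalysisConfig", "analyze_cell", "analyze_cohort"]

E_REV_PUBLISHED = -60.6  # mV, reported sodium-current reversal, analysis constant
GAMMA_PS = 6.4  # pS, cited single-channel conductance
P_OPEN_RANGE = (0.4, 0.6)  # cited open probability at 0 mV


@dataclass(frozen=True)
class AnalysisConfig:
    """Analysis-side constants and mode flags.

    ``reversal_mode`` is explicit, never inferred: "published" carries
    ``e_rev_published`` verbatim through conductance and density arithmetic
    (reproducing the published derivation chain), "simulation" uses the
    reversal estimated from the I-V tail (or the simulator truth when
    supplied).
    """

    reversal_mode: str = "simulation"  # "simulation" | "published"
    e_rev_published: float = E_REV_PUBLISHED
    e_rev_truth: float | None = None  # simulator ground truth, if known
    gamma_pS: float = GAMMA_PS
    p_open_range: tuple[float, float] = P_OPEN_RANGE
    specific_capacitance: float = density.SPECIFIC_CAPACITANCE
    cell_area_um2: float = density.DEFAULT_CELL_AREA
    density_voltage: float = 0.0  # mV, test voltage for the density chain

    def __post_init__(self):
        if self.reversal_mode not in ("simulation", "published"):
            raise ValidationError("reversal_mode must be 'simulation' or 'published'")


def _reversal(config: AnalysisConfig, iv: activation.IVCurve) -> float:
    if config.reversal_mode == "published":
        return config.e_rev_published
    if config.e_rev_truth is not None:
        return config.e_rev_truth
    return activation.estimate_reversal(iv)


def analyze_cell(families: dict[str, SweepFamily],
                 config: AnalysisConfig = AnalysisConfig()) -> dict:
    """Analyze one cell's condition-labelled families.

    "control" is required.  When a blocking condition ("TTX" or "ProTxII")
    is present, the drug-sensitive component is isolated by subtraction and
    used for the activation/kinetics fits; otherwise the control traces are
    analyzed directly.
    """
    if "control" not in families:
        raise ValidationError("analyze_cell requires a 'control' family")
    control_fam = families["control"]
    proto = control_fam.protocol
    ctrl = preprocess_family(control_fam, "control")

    record: dict = {"cell_id": control_fam.cell_id,
                    "capacitance_pF": control_fam.membrane_capacitance,
                    "conditions": sorted(families)}

    # drug subtraction and percent inhibition at the 0 mV (or nearest) step
    ref_v = min(proto.test_voltages, key=lambda v: abs(v - 0.0))
    record["reference_voltage_mV"] = ref_v
    sens = dict(ctrl)
    record["percent_inhibition"] = {}
    for drug_label in ("TTX", "ProTxII"):
        if drug_label not in families:
            continue
        drug = preprocess_family(families[drug_label], drug_label)
        iso = isolation.isolate(ctrl[ref_v], drug[ref_v], proto.step_onset,
                                label=f"{drug_label}-S")
        record["percent_inhibition"][drug_label] = iso.percent_inhibition
        record[f"peak_{drug_label}S_pA"] = iso.peak_sensitive
        if drug_label == "TTX":
            # TTX-S component drives the activation/kinetics characterization
            sens = {v: isolation.subtract_traces(ctrl[v], drug[v], "TTX-S")
                    for v in proto.test_voltages}

    peak, peak_t = isolation.peak_amplitude(ctrl[ref_v], proto.step_onset)
    record["peak_pA"] = abs(peak)
    record["peak_signed_pA"] = peak
    if proto.step_duration >= isolation.PERSISTENT_AT_MS:
        record["persistent_pA"] = isolation.persistent_current(
            ctrl[ref_v], proto.step_onset)

    # kinetics at the reference voltage
    tau0 = None
    try:
        tf = kinetics.fit_inactivation_tau(sens[ref_v], proto.step_onset,
                                           proto.step_end)
        tau0 = tf.tau
        record["tau_0mV_ms"] = tau0
        record["time_to_peak_0mV_ms"] = kinetics.time_to_peak(
            sens[ref_v], proto.step_onset)
    except (ValidationError, activation.FitError):
        record["tau_0mV_ms"] = None

    # activation curve needs a multi-voltage family
    if len(proto.test_voltages) >= 4:
        iv = activation.build_iv(sens, proto.step_onset, condition="sensitive")
        record["iv_points"] = iv.points
        e_rev = _reversal(config, iv)
        record["e_rev_used_mV"] = e_rev
        try:
            gnorm = activation.conductance_curve(iv, e_rev)
            fit = activation.fit_boltzmann(gnorm, e_rev_used=e_rev)
            record["v_half_mV"] = fit.v_half
            record["k_mV"] = fit.k
            record["boltzmann_residual_rms"] = fit.residual_rms
        except (ValidationError, activation.FitError) as e:
            record["boltzmann_error"] = str(e)
        thr = activation.activation_threshold(iv)
        record["activation_threshold_mV"] = thr
        taus, ttps = kinetics.tau_voltage_curve(sens, proto.step_onset,
                                                proto.step_end)
        record["tau_curve"] = taus
        record["ttp_curve"] = ttps

    # densities (measured-cell chain; the published-value chain is separate)
    cm = control_fam.membrane_capacitance
    if cm is not None:
        record["current_density_pA_pF"] = density.current_density(
            record["peak_pA"], cm)
        e_rev = record.get("e_rev_used_mV",
                           config.e_rev_published if config.reversal_mode == "published"
                           else config.e_rev_truth)
        if e_rev is not None:
            est = {}
            for po in config.p_open_range:
                d = density.estimate_density(
                    record["peak_pA"], cm, config.density_voltage, e_rev,
                    config.gamma_pS, po, config.specific_capacitance,
                    config.cell_area_um2)
                est[po] = dataclasses.asdict(d)
            record["density"] = est

    record["responder"] = density.classify_responder(record["peak_pA"], tau0)
    return record


def analyze_cohort(cells, config: AnalysisConfig = AnalysisConfig()) -> tuple[list[dict], density.CohortSummary]:
    """Run `analyze_cell` over a cohort and summarize it."""
    results = []
    for cell in cells:
        rec = analyze_cell({"control": cell.family}, config)
        rec["cell_id"] = cell.cell_id
        results.append(rec)
    return results, density.summarize_cohort(results)
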