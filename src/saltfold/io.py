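"""CSV interchange for the measured quantities.

Documented headers:

* equilibrium curves:   ``urea_M,signal``
* kinetic traces:       ``time_s,signal``
* chevron arm points:   ``urea_M,ku_per_s``
* rate vs salt points:  ``ionic_strength_M,ku_per_s``
* stability series:     ``ionic_strength_M,dG_kJ_mol[,dG_err_kJ_mol]``
* relaxation records:   ``residue,R1,R1_err,R1rho,R1rho_err,NOE,NOE_err,
  nu_SL_Hz,offset_Hz``

Metadata that is not a column (temperature, salt label) is supplied by the
caller or a sidecar config.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .equilibrium import DEFAULT_TEMPERATURE, DenaturationCurve, StabilitySeries
from .kinetics import KineticTrace
from .relaxation import RelaxationRecord

__all__ = [
    "read_denaturation_csv", "write_denaturation_csv",
    "read_trace_csv", "write_trace_csv",
    "read_arm_csv", "read_salt_rates_csv",
    "read_stability_csv", "write_stability_csv",
    "read_relaxation_csv", "write_relaxation_csv",
]


def read_denaturation_csv(path, temperature=DEFAULT_TEMPERATURE,
                          salt_label="", ionic_strength=0.0) -> DenaturationCurve:
    df = pd.read_csv(path)
    return DenaturationCurve(
        urea=df["urea_M"].to_numpy(), signal=df["signal"].to_numpy(),
        temperature=temperature, salt_label=salt_label,
        ionic_strength=ionic_strength,
    )


def write_denaturation_csv(curve: DenaturationCurve, path) -> None:
    pd.DataFrame({"urea_M": curve.urea, "signal": curve.signal}).to_csv(
        path, index=False)


def read_trace_csv(path, urea=0.0, ionic_strength=0.0,
                   temperature=DEFAULT_TEMPERATURE) -> KineticTrace:
    df = pd.read_csv(path)
    return KineticTrace(
        time=df["time_s"].to_numpy(), signal=df["signal"].to_numpy(),
        urea=urea, ionic_strength=ionic_strength, temperature=temperature,
    )


def write_trace_csv(trace: KineticTrace, path) -> None:
    pd.DataFrame({"time_s": trace.time, "signal": trace.signal}).to_csv(
        path, index=False)


def read_arm_csv(path):
    df = pd.read_csv(path)
    return list(zip(df["urea_M"], df["ku_per_s"]))


def read_salt_rates_csv(path):
    df = pd.read_csv(path)
    return list(zip(df["ionic_strength_M"], df["ku_per_s"]))


def read_stability_csv(path, salt_type="NaCl") -> StabilitySeries:
    df = pd.read_csv(path)
    err = df["dG_err_kJ_mol"].to_numpy() if "dG_err_kJ_mol" in df else None
    return StabilitySeries(
        ionic_strength=df["ionic_strength_M"].to_numpy(),
        dG=df["dG_kJ_mol"].to_numpy(), dG_errors=err, salt_type=salt_type,
    )


def write_stability_csv(series: StabilitySeries, path) -> None:
    data = {"ionic_strength_M": series.ionic_strength,
            "dG_kJ_mol": series.dG}
    if series.dG_errors is not None:
        data["dG_err_kJ_mol"] = series.dG_errors
    pd.DataFrame(data).to_csv(path, index=False)


def read_relaxation_csv(path) -> list[RelaxationRecord]:
    df = pd.read_csv(path)
    records = []
    for _, row in df.iterrows():
        records.append(RelaxationRecord(
            residue=int(row["residue"]),
            R1=float(row["R1"]), R1rho=float(row["R1rho"]),
            NOE=float(row["NOE"]),
            nu_SL=float(row.get("nu_SL_Hz", 2000.0)),
            Omega=float(row.get("offset_Hz", 0.0)),
            R1_err=float(row.get("R1_err", np.nan)),
            R1rho_err=float(row.get("R1rho_err", np.nan)),
            NOE_err=float(row.get("NOE_err", np.nan)),
        ))
    return records


def write_relaxation_csv(records, path) -> None:
    pd.DataFrame([
        {
            "residue": r.residue, "R1": r.R1, "R1_err": r.R1_err,
            "R1rho": r.R1rho, "R1rho_err": r.R1rho_err,
            "NOE": r.NOE, "NOE_err": r.NOE_err,
            "nu_SL_Hz": r.nu_SL, "offset_Hz": r.Omega,
        }
        for r in records
    ]).to_csv(path, index=False)
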