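"""Per-patient relapse reports.

A patient table is a tab-delimited file of normalized expression values
with signature genes as columns and patients as rows.  Each patient
gets a relapse score, a risk group from the calibrated thresholds, and
an estimated 10-year relapse likelihood (with 95% CI) read off the
calibration curve.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .calibration import CalibrationBundle, assign_groups
from .containers import ExpressionMatrix, InputError

logger = logging.getLogger(__name__)


def read_patient_table(path: str | Path, required_genes=None) -> ExpressionMatrix:
    """Read a patients x genes expression table.

    The header row names the genes; the first column holds patient ids.
    When ``required_genes`` is given, missing genes are an error listed
    by name and extra columns are kept with a warning.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    bad = df.map(lambda v: not isinstance(v, (int, float)))
    if bad.to_numpy().any():
        r, c = next(zip(*bad.to_numpy().nonzero()))
        raise InputError(
            f"non-numeric value at row {df.index[r]!r}, column {df.columns[c]!r} in {path.name}"
        )
    if required_genes is not None:
        missing = [g for g in required_genes if g not in df.columns]
        if missing:
            raise InputError(f"patient table {path.name} is missing genes: {missing}")
        extra = [c for c in df.columns if c not in set(required_genes)]
        if extra:
            logger.warning("ignoring %d extra column(s) not in the signature: %s",
                           len(extra), extra[:5])
    return ExpressionMatrix(df.astype(float), {g: g for g in df.columns})


def make_report(scores: pd.Series, calibration: CalibrationBundle,
                model_id: str = "rfrs", signature_id: str = "") -> pd.DataFrame:
    """Build the per-patient report table.

    Columns: sample_id, rfrs, risk_group, likelihood, ci_low, ci_high,
    out_of_curve_support flag, plus the thresholds and identifiers
    used.  Scores outside the fitted curve support get the nearest
    endpoint's likelihood and are flagged.
    """
    thresholds = calibration.thresholds
    groups = assign_groups(scores, thresholds)
    rows = []
    for sid, sc in scores.items():
        lik, lo, hi = calibration.curve.lookup(float(sc))
        rows.append(
            {
                "sample_id": sid,
                "rfrs": float(sc),
                "risk_group": groups[sid],
                "likelihood": lik,
                "ci_low": lo,
                "ci_high": hi,
                "out_of_curve_support": not calibration.curve.in_support(float(sc)),
                "t_low": thresholds.t_low,
                "t_high": thresholds.t_high,
                "model": model_id,
                "signature": signature_id,
            }
        )
    return pd.DataFrame(rows)


def format_report(report: pd.DataFrame) -> str:
    """Human-readable rendering of a report table."""
    lines = []
    for _, r in report.iterrows():
        flag = " (score outside calibration support)" if r["out_of_curve_support"] else ""
        lines.append(
            f"Patient {r['sample_id']}: RFRS = {r['rfrs']:.3f} -> {r['risk_group']}-risk "
            f"(thresholds {r['t_low']:.3f}/{r['t_high']:.3f}); estimated 10-year relapse "
            f"likelihood {100 * r['likelihood']:.1f}% "
            f"[95% CI {100 * r['ci_low']:.1f}-{100 * r['ci_high']:.1f}%]{flag}"
        )
    return "\n".join(lines)
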