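"""Phase-diagram tables over (qa, qc) grids."""

from __future__ import annotations

import pandas as pd

from .stationary import classify_transition

__all__ = ["build_diagram"]

COLUMNS = ["qa", "qc", "p1_star", "p_star", "p2_star", "width", "type"]


def build_diagram(qa_values, qc_values) -> pd.DataFrame:
    """One row per (qa, qc) pair: spinodals, transition point, type, width.

    Deterministic; module errors are re-raised with the offending pair
    attached.
    """
    qa_values = list(qa_values)
    qc_values = list(qc_values)
    if not qa_values or not qc_values:
        raise ValueError("qa_values and qc_values must be nonempty")
    rows = []
    for qa in qa_values:
        for qc in qc_values:
            try:
                s = classify_transition(qa, qc)
            except Exception as exc:  # noqa: BLE001 — context, then re-raise
                raise type(exc)(f"(qa={qa}, qc={qc}): {exc}") from exc
            rows.append(
                {
                    "qa": s.qa,
                    "qc": s.qc,
                    "p1_star": s.p1_star,
                    "p_star": s.p_star,
                    "p2_star": s.p2_star,
                    "width": s.width,
                    "type": s.transition_type,
                }
            )
    return pd.DataFrame(rows, columns=COLUMNS)
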