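"""Data ingestion and fit reporting.

CSV in (comma-separated, header row, UTF-8, decimal point), JSON + text
reports out.  The text report mirrors the conventional coefficient-table
layout for these models: a "Zero part" block (logistic coefficients, with
odds ratios for a non-zero outcome and their reciprocal, the odds of a
zero), a "Continuous Non-zero part" block (log-scale coefficients with
their exponentiated multiplicative effects), and a "Random effects" block.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .inference import FitResult
from .model import ModelSpec, PanelDataset

__all__ = ["ColumnMapping", "read_panel_table", "write_fit_report"]

logger = logging.getLogger("mtplong")


@dataclass
class ColumnMapping:
    """Which input columns play which role.

    ``z``/``x``/``w`` are covariate column names for the binary part, the
    continuous part and the one-part model; an intercept is prepended
    automatically.  ``w`` defaults to ``x``.
    """

    subject: str
    time: str
    outcome: str
    z: list = field(default_factory=list)
    x: list = field(default_factory=list)
    w: list | None = None
    zero_threshold: float = 0.0


def read_panel_table(path, mapping: ColumnMapping) -> PanelDataset:
    """Read a long-format delimited table into a :class:`PanelDataset`.

    Rows with missing values in any used column are dropped (complete case)
    with a logged count, available afterwards as ``dataset.n_dropped``.
    """
    df = pd.read_csv(path)
    w_cols = mapping.w if mapping.w is not None else mapping.x
    used = [mapping.subject, mapping.time, mapping.outcome]
    used += list(dict.fromkeys(list(mapping.z) + list(mapping.x) + list(w_cols)))
    missing = [c for c in used if c not in df.columns]
    if missing:
        raise ValueError(f"mapped column(s) not in input: {missing}")

    n_in = len(df)
    sub = df[used].copy()
    for c in used:
        if c != mapping.subject:
            sub[c] = pd.to_numeric(sub[c], errors="coerce")
    keep = sub.notna().all(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropped %d row(s) with missing values in used columns", n_dropped)
    sub = sub[keep]
    if len(sub) == 0:
        raise ValueError("no complete rows left after dropping missing values")

    y = sub[mapping.outcome].to_numpy(dtype=float)
    neg = np.flatnonzero(y < 0)
    if len(neg):
        raise ValueError(
            f"negative outcome at input row {sub.index[neg[0]]}: {y[neg[0]]}"
        )

    def design(cols):
        M = np.column_stack([np.ones(len(sub))] +
                            [sub[c].to_numpy(dtype=float) for c in cols])
        return M

    ds = PanelDataset(
        subject=sub[mapping.subject].to_numpy(),
        time=sub[mapping.time].to_numpy(dtype=float),
        y=y,
        Z=design(mapping.z),
        X=design(mapping.x),
        W=design(w_cols) if mapping.w is not None else None,
    )
    ds.n_dropped = n_dropped
    ds.n_input_rows = n_in
    return ds


def _p_str(p: float) -> str:
    if not np.isfinite(p):
        return "   NA"
    return "< 0.0001" if p < 0.0001 else f"{p:.4f}"


def _partition(fit: FitResult):
    zero, cont, other = [], [], []
    for i, name in enumerate(fit.param_names):
        if name.startswith("alpha"):
            zero.append(i)
        elif name.startswith(("cont", "coef", "beta", "gamma", "delta")):
            cont.append(i)
        else:
            other.append(i)
    return zero, cont, other


def write_fit_report(fit: FitResult, spec: ModelSpec | None, destination):
    """Write JSON + text reports of a fit; returns (json_path, text_path)."""
    spec = spec or fit.spec
    dest = Path(destination)
    dest.mkdir(parents=True, exist_ok=True)
    json_path = dest / "fit_report.json"
    text_path = dest / "fit_report.txt"

    pvals = fit.wald_pvalues()
    payload = {
        "family": spec.family,
        "distribution": spec.distribution,
        "param_names": list(fit.param_names),
        "estimates": [float(v) for v in fit.natural],
        "se": [None if not np.isfinite(s) else float(s) for s in fit.se],
        "p_values": [None if not np.isfinite(p) else float(p) for p in pvals],
        "vcov": [[float(v) for v in row] for row in np.asarray(fit.vcov)],
        "loglik": float(fit.loglik),
        "neg2loglik": float(fit.neg2loglik),
        "aic": float(fit.aic),
        "bic": float(fit.bic),
        "n_params": int(fit.n_params),
        "n_subjects": int(fit.n_subjects),
        "converged": bool(fit.converged),
        "n_iter": int(fit.n_iter),
        "gradient_norm": float(fit.gradient_norm),
        "messages": list(fit.messages),
    }
    json_path.write_text(json.dumps(payload, indent=2))

    zero, cont, other = _partition(fit)
    lines = []
    title = f"{spec.family} model, {spec.distribution} continuous part"
    lines.append(title)
    lines.append("=" * len(title))
    if not fit.converged:
        lines.append("*** WARNING: OPTIMIZER DID NOT CONVERGE — estimates unreliable ***")
    lines.append(f"subjects: {fit.n_subjects}   free parameters: {fit.n_params}")
    lines.append(
        f"-2 logLik: {fit.neg2loglik:.4f}   AIC: {fit.aic:.4f}   BIC: {fit.bic:.4f}"
    )
    lines.append("")

    def block(title, idxs, exp_label, reciprocal=False):
        if not idxs:
            return
        lines.append(title)
        lines.append("-" * len(title))
        hdr = f"{'term':<24}{'estimate':>12}{'SE':>12}{'P-value':>12}{exp_label:>14}"
        if reciprocal:
            hdr += f"{'odds(zero)':>14}"
        lines.append(hdr)
        for i in idxs:
            est, se, p = fit.natural[i], fit.se[i], pvals[i]
            se_s = f"{se:.4f}" if np.isfinite(se) else "NA"
            row = (f"{fit.param_names[i]:<24}{est:>12.4f}{se_s:>12}"
                   f"{_p_str(p):>12}{np.exp(est):>14.4f}")
            if reciprocal:
                row += f"{np.exp(-est):>14.4f}"
            lines.append(row)
        lines.append("")

    block("Zero part (P(Y > 0), logistic)", zero, "OR(non-zero)", reciprocal=True)
    label = ("exp(beta): effect on the marginal mean E(Y)"
             if spec.family == "mtp" else "exp(coef)")
    block("Continuous Non-zero part", cont, "exp(coef)")
    if spec.family == "mtp" and cont:
        lines.append(f"  note: {label}, zeros included")
        lines.append("")

    if other:
        lines.append("Random effects / distribution")
        lines.append("-" * 30)
        for i in other:
            se = fit.se[i]
            se_s = f"{se:.4f}" if np.isfinite(se) else "NA"
            lines.append(f"{fit.param_names[i]:<24}{fit.natural[i]:>12.4f}{se_s:>12}")
        lines.append("")
    for m in fit.messages:
        lines.append(f"note: {m}")
    text_path.write_text("\n".join(lines) + "\n")
    return json_path, text_path
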