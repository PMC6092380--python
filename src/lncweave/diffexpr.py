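"""TPM computation, scaling normalization and divergent-family DE calling.

Testing is count-based: each pooled family library contributes one column of
negative-binomially distributed counts, and a two-group exact conditional
test is run on the group sums after library-size adjustment.  TPM is
computed for reporting and for the co-expression stage; fold changes use the
signed convention (ratios below 1 are reported as -1/ratio) so the
significance rule reads "q < 0.05 and FC >= 2 or <= -2".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import ExpressionMatrix
from .phenotype import ContrastDesign

DEFAULT_FDR = 0.05
DEFAULT_FC = 2.0
DISPERSION_FLOOR = 0.01
FC_PSEUDOCOUNT = 0.5


@dataclass
class DEResult:
    transcript_id: str
    mean_high: float
    mean_low: float
    fold_change: float  # signed: |FC| >= 1, negative means higher in the low group
    log2_fc: float
    p_value: float
    q_value: float
    is_de: bool
    trait: str = ""


def compute_tpm(counts: ExpressionMatrix, lengths: dict[str, float] | pd.Series) -> ExpressionMatrix:
    """Transcripts-per-million: length-rate normalization, columns sum to 1e6."""
    if counts.unit != "counts":
        raise ValueError("compute_tpm expects a counts matrix")
    lens = pd.Series(lengths, dtype=float).reindex(counts.values.index)
    if lens.isna().any():
        missing = list(lens.index[lens.isna()])[:5]
        raise ValueError(f"missing transcript lengths, e.g. {missing}")
    if (lens <= 0).any():
        raise ValueError("all transcript lengths must be > 0")
    rates = counts.values.div(lens, axis=0)
    col_sums = rates.sum(axis=0)
    if (col_sums == 0).any():
        dead = list(col_sums.index[col_sums == 0])
        raise ValueError(f"all-zero count columns have undefined TPM: {dead}")
    tpm = rates.div(col_sums, axis=1) * 1e6
    return ExpressionMatrix(values=tpm, unit="TPM")


def normalize_scaling(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Per-library scaling to the grand-mean column sum (upstream of correlation)."""
    if matrix.unit != "TPM":
        raise ValueError("normalize_scaling expects a TPM matrix")
    sums = matrix.values.sum(axis=0)
    if (sums == 0).any():
        raise ValueError("zero column sum cannot be scaled")
    factors = sums.mean() / sums
    return ExpressionMatrix(values=matrix.values.mul(factors, axis=1), unit="scaled")


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order."""
    p = np.asarray(pvalues, float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def nb_exact_test(
    counts_a, sizes_a, counts_b, sizes_b, dispersion: float = 0.0
) -> float:
    """Exact conditional two-group test on library-size-adjusted count sums.

    The group sums are modelled as negative binomial (Poisson at
    ``dispersion`` 0); conditioning on the total gives a discrete
    distribution over how the total splits between groups, evaluated by
    direct summation.  The two-sided p doubles the smaller tail (point
    included), capped at 1.
    """
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    counts_a, counts_b = np.asarray(counts_a, float), np.asarray(counts_b, float)
    sizes_a, sizes_b = np.asarray(sizes_a, float), np.asarray(sizes_b, float)
    if counts_a.size == 0 or counts_b.size == 0:
        raise ValueError("each group needs at least one library")
    ya = int(round(counts_a.sum()))
    yb = int(round(counts_b.sum()))
    t = ya + yb
    if t == 0:
        return 1.0
    sa, sb = float(sizes_a.sum()), float(sizes_b.sum())
    if sa <= 0 or sb <= 0:
        raise ValueError("library sizes must be positive")

    if dispersion == 0.0:
        dist = stats.binom(t, sa / (sa + sb))
        lo = dist.cdf(ya)
        hi = dist.sf(ya - 1)
    else:
        lam = t / (sa + sb)
        k = np.arange(t + 1)
        # sum of n iid NB(mu, phi) is NB(n*mu, phi/n)
        logw = _nb_logpmf(k, sa * lam, dispersion / counts_a.size) + _nb_logpmf(
            t - k, sb * lam, dispersion / counts_b.size
        )
        w = np.exp(logw - logw.max())
        w /= w.sum()
        lo = w[: ya + 1].sum()
        hi = w[ya:].sum()
    return float(min(1.0, 2.0 * min(lo, hi)))


def _nb_logpmf(k, mu, phi):
    r = 1.0 / phi
    return stats.nbinom.logpmf(k, r, r / (r + mu))


def estimate_dispersion(counts: pd.DataFrame, groups: list[list[str]], floor: float = DISPERSION_FLOOR) -> float:
    """Common dispersion: median of per-transcript moment estimates.

    Within each group, counts are library-size-normalized and
    phi_t = (s^2 - m)/m^2 is computed per transcript; the common value is
    the median over all (transcript, group) estimates with m > 0, floored.
    The median keeps a handful of genuinely high-variance transcripts from
    inflating the common value for everything else.
    """
    estimates = []
    for cols in groups:
        sub = counts[cols]
        if len(cols) < 2:
            continue
        sizes = sub.sum(axis=0)
        norm = sub.div(sizes / sizes.mean(), axis=1)
        m = norm.mean(axis=1).to_numpy()
        v = norm.var(axis=1, ddof=1).to_numpy()
        keep = m > 0
        estimates.append((v[keep] - m[keep]) / m[keep] ** 2)
    if not estimates:
        return floor
    pooled = np.concatenate(estimates)
    if pooled.size == 0:
        return floor
    return max(floor, float(np.median(pooled)))


def signed_fold_change(mean_high: float, mean_low: float, pseudocount: float = FC_PSEUDOCOUNT) -> float:
    ratio = (mean_high + pseudocount) / (mean_low + pseudocount)
    return ratio if ratio >= 1.0 else -1.0 / ratio


def call_de(
    counts: ExpressionMatrix,
    design: ContrastDesign,
    dispersion: float | str = "auto",
    fdr_cutoff: float = DEFAULT_FDR,
    fc_cutoff: float = DEFAULT_FC,
    pseudocount: float = FC_PSEUDOCOUNT,
) -> list[DEResult]:
    """Per-transcript DE calls for one 4-vs-4 (or k-vs-k) divergent contrast.

    Transcripts with zero counts in both groups are excluded from testing
    and from the BH family size.  FDR is controlled per contrast.
    """
    if counts.unit != "counts":
        raise ValueError("call_de tests counts; compute TPM separately for reporting")
    df = counts.values
    missing = [c for c in design.high + design.low if c not in df.columns]
    if missing:
        raise ValueError(f"design libraries absent from matrix: {missing}")
    high, low = df[design.high], df[design.low]
    sizes_h, sizes_l = high.sum(axis=0).to_numpy(), low.sum(axis=0).to_numpy()

    tested = (high.sum(axis=1) + low.sum(axis=1)) > 0
    ids = list(df.index[tested])
    if dispersion == "auto":
        phi = estimate_dispersion(df, [design.high, design.low])
    else:
        phi = float(dispersion)

    # library-size-normalized means for fold changes (per-million scale)
    mh = (high.div(sizes_h / 1e6, axis=1)).mean(axis=1)
    ml = (low.div(sizes_l / 1e6, axis=1)).mean(axis=1)

    pvals = np.array(
        [
            nb_exact_test(high.loc[tid].to_numpy(), sizes_h, low.loc[tid].to_numpy(), sizes_l, phi)
            for tid in ids
        ]
    )
    qvals = bh_fdr(pvals)

    results = []
    for tid, p, q in zip(ids, pvals, qvals):
        fc = signed_fold_change(float(mh[tid]), float(ml[tid]), pseudocount)
        log2fc = np.log2(abs(fc)) * (1 if fc > 0 else -1)
        is_de = (q < fdr_cutoff) and (fc >= fc_cutoff or fc <= -fc_cutoff)
        results.append(
            DEResult(
                transcript_id=tid,
                mean_high=float(mh[tid]),
                mean_low=float(ml[tid]),
                fold_change=float(fc),
                log2_fc=float(log2fc),
                p_value=float(p),
                q_value=float(q),
                is_de=bool(is_de),
                trait=design.trait,
            )
        )
    return results
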