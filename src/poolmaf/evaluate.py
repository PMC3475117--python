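"""Scoring calls against simulated truth, and site-frequency spectra.

Power is the proportion of true segregating sites (within the depth
window) that are called; FDR is the proportion of calls that do not
coincide with a true segregating site.  Eligibility uses the realized
used depth C — the same number the caller sees — so a true site with too
few or too many reads is excluded from both numerator and denominator,
matching the fact that calling itself is restricted to the window.

The spectra compare the folded site-frequency spectrum of the pooled
sample (subsampled to mimic the read depth) with the spectrum implied by
raw read frequencies at called sites of one exact depth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd

from .simulate import TruthTable

__all__ = [
    "Metrics",
    "SFSEstimate",
    "apply_threshold",
    "score_calls",
    "bin_metrics",
    "true_pooled_sfs",
    "estimated_sfs",
]


@dataclass
class Metrics:
    """Power/FDR summary; ``power`` or ``fdr`` is None when its
    denominator is zero (undefined)."""

    power: Optional[float]
    fdr: Optional[float]
    n_true_eligible: int
    n_called: int
    n_true_positive: int


@dataclass
class SFSEstimate:
    """Folded (or unfolded) site-frequency spectrum.

    ``counts[j]`` is the number of sites in allele-count class ``j`` out
    of ``n_alleles``; for a folded spectrum only classes 1..n_alleles//2
    are populated.
    """

    n_alleles: int
    folded: bool
    counts: np.ndarray
    depth_restriction: Optional[int] = None

    def frame(self) -> pd.DataFrame:
        hi = self.n_alleles // 2 if self.folded else self.n_alleles - 1
        classes = np.arange(1, hi + 1)
        return pd.DataFrame({
            "allele_count": classes,
            "frequency": classes / self.n_alleles,
            "n_sites": self.counts[classes],
        })


def _truth_frame(truth: Union[TruthTable, pd.DataFrame]) -> pd.DataFrame:
    if isinstance(truth, TruthTable):
        return truth.frame()
    return truth


def apply_threshold(calls: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Re-derive the ``called`` flag at a different segregation threshold."""
    out = calls.copy()
    out["called"] = out["p_seg"] > threshold
    return out


def _check_region(calls: pd.DataFrame,
                  truth: Union[TruthTable, pd.DataFrame]) -> None:
    if isinstance(truth, TruthTable) and len(calls):
        labels = set(calls["chrom"].unique())
        if labels - {truth.config.chrom}:
            raise ValueError(
                f"calls refer to {sorted(labels)} but truth describes "
                f"{truth.config.chrom!r}"
            )


def score_calls(calls: pd.DataFrame, truth: Union[TruthTable, pd.DataFrame],
                min_depth: int = 5, max_depth: int = 40) -> Metrics:
    """Overall power and FDR within the depth window.

    ``calls`` must contain one row per analysed site (called or not) with
    columns pos, C and called; rows outside the window are ignored.
    """
    _check_region(calls, truth)
    tf = _truth_frame(truth)
    window = calls[(calls["C"] >= min_depth) & (calls["C"] <= max_depth)]
    truth_pos = tf["pos"].to_numpy()
    eligible = np.isin(truth_pos, window["pos"].to_numpy())
    called_pos = window.loc[window["called"], "pos"].to_numpy()
    tp = int(np.isin(truth_pos, called_pos).sum())
    n_eligible = int(eligible.sum())
    n_called = int(len(called_pos))
    power = tp / n_eligible if n_eligible else None
    fdr = (n_called - tp) / n_called if n_called else None
    return Metrics(power=power, fdr=fdr, n_true_eligible=n_eligible,
                   n_called=n_called, n_true_positive=tp)


def bin_metrics(calls: pd.DataFrame, truth: Union[TruthTable, pd.DataFrame],
                by: str = "depth", min_depth: int = 5,
                max_depth: int = 40) -> pd.DataFrame:
    """Power (and, for depth bins, FDR) broken down by realized depth or
    by true sample minor-allele frequency.

    Depth bins are one read wide over [min_depth, max_depth]; MAF bins
    are 0.05 wide over (0, 0.5] using min(k, N-k)/N.
    """
    _check_region(calls, truth)
    tf = _truth_frame(truth)
    window = calls[(calls["C"] >= min_depth) & (calls["C"] <= max_depth)]
    called_pos = window.loc[window["called"], "pos"].to_numpy()
    depth_at = dict(zip(window["pos"].to_numpy(), window["C"].to_numpy()))

    truth_pos = tf["pos"].to_numpy()
    truth_depth = np.array([depth_at.get(p, -1) for p in truth_pos])
    truth_called = np.isin(truth_pos, called_pos)
    eligible = truth_depth >= 0

    rows = []
    if by == "depth":
        call_depths = window.loc[window["called"], "C"].to_numpy()
        fp_flags = ~np.isin(called_pos, truth_pos)
        for d in range(min_depth, max_depth + 1):
            in_bin = eligible & (truth_depth == d)
            n_elig = int(in_bin.sum())
            n_tp = int((in_bin & truth_called).sum())
            at_d = call_depths == d
            n_call = int(at_d.sum())
            n_fp = int(fp_flags[at_d].sum())
            rows.append({
                "bin": d,
                "n_true_eligible": n_elig,
                "n_true_positive": n_tp,
                "power": n_tp / n_elig if n_elig else np.nan,
                "n_called": n_call,
                "fdr": n_fp / n_call if n_call else np.nan,
            })
    elif by == "maf":
        n_pool = tf["N"].to_numpy()
        maf = np.minimum(tf["k"].to_numpy(), n_pool - tf["k"].to_numpy()) / n_pool
        edges = np.arange(0.0, 0.5001, 0.05)
        for lo, hi in zip(edges[:-1], edges[1:]):
            in_bin = eligible & (maf > lo) & (maf <= hi)
            n_elig = int(in_bin.sum())
            n_tp = int((in_bin & truth_called).sum())
            rows.append({
                "bin": hi,
                "n_true_eligible": n_elig,
                "n_true_positive": n_tp,
                "power": n_tp / n_elig if n_elig else np.nan,
            })
    else:
        raise ValueError(f"unknown binning {by!r}; use 'depth' or 'maf'")
    return pd.DataFrame(rows)


def true_pooled_sfs(truth: Union[TruthTable, pd.DataFrame], n_sub: int = 20,
                    seed: int = 0, folded: bool = True) -> SFSEstimate:
    """Folded SFS of the pooled sample after binomial subsampling.

    Each true site contributes a draw of ``n_sub`` chromosomes with
    replacement (alternative with probability k/N); sites monomorphic in
    the subsample are excluded.  This mimics what a perfect caller could
    see at read depth ``n_sub``.
    """
    if n_sub < 2:
        raise ValueError("subsample size must be >= 2")
    tf = _truth_frame(truth)
    rng = np.random.default_rng(seed)
    counts = np.zeros(n_sub + 1, dtype=np.int64)
    if len(tf):
        p = tf["k"].to_numpy() / tf["N"].to_numpy()
        j = rng.binomial(n_sub, p)
        j = j[(j > 0) & (j < n_sub)]
        if folded:
            j = np.minimum(j, n_sub - j)
        counts += np.bincount(j, minlength=n_sub + 1)
    return SFSEstimate(n_alleles=n_sub, folded=folded, counts=counts)


def estimated_sfs(calls: pd.DataFrame, exact_depth: int = 20,
                  folded: bool = True) -> SFSEstimate:
    """SFS implied by raw read frequencies at called sites of one depth.

    Only called sites with ``C == exact_depth`` enter; each contributes
    its alternative read count ``n_A`` (folded to min(n_A, C - n_A)).
    """
    sel = calls[(calls["called"]) & (calls["C"] == exact_depth)
                & (calls["n_A"] > 0) & (calls["n_A"] < calls["C"])]
    j = sel["n_A"].to_numpy(dtype=np.int64)
    if folded:
        j = np.minimum(j, exact_depth - j)
    counts = np.bincount(j, minlength=exact_depth + 1)
    return SFSEstimate(n_alleles=exact_depth, folded=folded, counts=counts,
                       depth_restriction=exact_depth)
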