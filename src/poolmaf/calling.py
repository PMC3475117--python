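"""Batch SNP calling over many sites.

The per-site model lives in :mod:`poolmaf.model`; this module evaluates it
vectorized over whole tables of sites so that megabase-scale pileups and
simulation benchmarks run in seconds.  The arithmetic is identical to the
scalar path (the test suite asserts agreement): per-read binomial terms
are formed in log space, shifted by the per-site maximum over the pool
composition k, and combined with the pooling kernel by a single matrix
product.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, TextIO, Union

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .errors import EPS_CEIL, EPS_FLOOR, DEFAULT_FALLBACK_EPS
from .model import Distribution, FrequencyGrid, PriorSpec, build_prior
from .pileup import SiteCounts, iter_pileup, reduce_to_counts

__all__ = [
    "RESULT_COLUMNS",
    "CallBatch",
    "class_rates_batch",
    "pooling_kernel",
    "batch_call",
    "counts_to_frame",
    "call_pileup",
    "write_calls",
    "read_calls",
]

RESULT_COLUMNS = [
    "chrom", "pos", "ref", "alt", "C", "n_A", "eps_R", "eps_A",
    "p_f0", "p_f1", "p_seg", "mean_f", "map_f", "called",
]


@dataclass
class CallBatch:
    """Result of a batch call: per-site summaries and, optionally, the
    full posterior matrix (sites x grid)."""

    results: pd.DataFrame
    posteriors: Optional[np.ndarray] = None


def class_rates_batch(site_idx: np.ndarray, is_alt: np.ndarray,
                      err_prob: np.ndarray, n_sites: int,
                      fallback: float = DEFAULT_FALLBACK_EPS
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Per-site geometric-mean class error rates for flattened read arrays.

    ``site_idx`` maps each read to its site; ``is_alt`` flags reads in the
    alternative class; ``err_prob`` is the Phred-implied error probability
    of each read.  Empty classes fall back to the site-wide geometric mean
    (or ``fallback`` for empty sites); results are clamped to
    [EPS_FLOOR, EPS_CEIL] like the scalar path.
    """
    logp = np.log(err_prob)
    cnt_all = np.bincount(site_idx, minlength=n_sites).astype(float)
    sum_all = np.bincount(site_idx, weights=logp, minlength=n_sites)
    cnt_a = np.bincount(site_idx[is_alt], minlength=n_sites).astype(float)
    sum_a = np.bincount(site_idx[is_alt], weights=logp[is_alt],
                        minlength=n_sites)
    cnt_r = cnt_all - cnt_a
    sum_r = sum_all - sum_a

    with np.errstate(invalid="ignore", divide="ignore"):
        site_fb = np.where(cnt_all > 0,
                           np.exp(sum_all / np.maximum(cnt_all, 1.0)),
                           fallback)
        eps_a = np.where(cnt_a > 0,
                         np.exp(sum_a / np.maximum(cnt_a, 1.0)), site_fb)
        eps_r = np.where(cnt_r > 0,
                         np.exp(sum_r / np.maximum(cnt_r, 1.0)), site_fb)
    eps_a = np.clip(eps_a, EPS_FLOOR, EPS_CEIL)
    eps_r = np.clip(eps_r, EPS_FLOOR, EPS_CEIL)
    return eps_r, eps_a


def pooling_kernel(N: int, grid: FrequencyGrid) -> np.ndarray:
    """Binom(k; N, f) for k = 0..N (rows) and f on the grid (columns)."""
    k = np.arange(N + 1)
    f = grid.values
    with np.errstate(divide="ignore", invalid="ignore"):
        log_pool = (
            gammaln(N + 1) - gammaln(k + 1) - gammaln(N - k + 1)
        )[:, None] + k[:, None] * np.log(f[None, :]) \
            + (N - k)[:, None] * np.log1p(-f[None, :])
    log_pool = np.where(np.isnan(log_pool), -np.inf, log_pool)
    log_pool[0, 0] = 0.0
    log_pool[N, -1] = 0.0
    return np.exp(log_pool)


def batch_call(frame: pd.DataFrame, N: int, prior: Union[Distribution, PriorSpec],
               threshold: float = 0.9, return_posteriors: bool = False,
               chunk_size: int = 65536) -> CallBatch:
    """Call every site in a counts table.

    ``frame`` needs columns chrom, pos, ref, alt, C, n_A, eps_R, eps_A
    (see :func:`counts_to_frame` and the simulator's fast path).
    """
    if isinstance(prior, PriorSpec):
        prior = build_prior(prior)
    grid = prior.grid
    f = grid.values
    kernel = pooling_kernel(N, grid)
    kn = np.arange(N + 1) / N

    n = len(frame)
    C = frame["C"].to_numpy(dtype=np.int64)
    n_A = frame["n_A"].to_numpy(dtype=np.int64)
    eps_r = frame["eps_R"].to_numpy(dtype=float)
    eps_a = frame["eps_A"].to_numpy(dtype=float)

    p_f0 = np.empty(n)
    p_f1 = np.empty(n)
    p_seg = np.empty(n)
    mean_f = np.empty(n)
    map_f = np.empty(n)
    posteriors = np.empty((n, len(grid))) if return_posteriors else None

    log_binom_coeff = gammaln(C + 1) - gammaln(n_A + 1) - gammaln(C - n_A + 1)

    for start in range(0, n, chunk_size):
        sl = slice(start, min(start + chunk_size, n))
        denom = 1.0 - eps_a[sl] - eps_r[sl]
        rho = eps_r[sl] * (1.0 - 2.0 * eps_a[sl]) / denom
        alpha = eps_a[sl] * (1.0 - 2.0 * eps_r[sl]) / denom
        # p_tilde in (0, 1) is guaranteed by the class-rate clamp
        p_t = (1.0 - rho)[:, None] * kn[None, :] \
            + alpha[:, None] * (1.0 - kn[None, :])
        log_read = (
            log_binom_coeff[sl][:, None]
            + n_A[sl][:, None] * np.log(p_t)
            + (C - n_A)[sl][:, None] * np.log1p(-p_t)
        )
        shift = log_read.max(axis=1)
        read_pmf = np.exp(log_read - shift[:, None])
        lik = read_pmf @ kernel  # scaled likelihood; scale cancels below
        unnorm = lik * prior.mass[None, :]
        total = unnorm.sum(axis=1)
        if np.any(total <= 0) or not np.all(np.isfinite(total)):
            bad = frame.iloc[sl].loc[
                ~np.isfinite(total) | (total <= 0), ["chrom", "pos"]]
            raise FloatingPointError(
                f"posterior vanished at {len(bad)} site(s), first: "
                f"{bad.iloc[0]['chrom']}:{bad.iloc[0]['pos']}"
            )
        post = unnorm / total[:, None]
        p_f0[sl] = post[:, 0]
        p_f1[sl] = post[:, -1]
        p_seg[sl] = post[:, 1:-1].sum(axis=1)
        mean_f[sl] = post @ f
        map_f[sl] = f[np.argmax(post, axis=1)]
        if posteriors is not None:
            posteriors[sl] = post

    results = pd.DataFrame({
        "chrom": frame["chrom"].to_numpy(),
        "pos": frame["pos"].to_numpy(),
        "ref": frame["ref"].to_numpy(),
        "alt": frame["alt"].to_numpy(),
        "C": C,
        "n_A": n_A,
        "eps_R": eps_r,
        "eps_A": eps_a,
        "p_f0": p_f0,
        "p_f1": p_f1,
        "p_seg": p_seg,
        "mean_f": mean_f,
        "map_f": map_f,
        "called": p_seg > threshold,
    })
    return CallBatch(results=results, posteriors=posteriors)


def counts_to_frame(counts: Iterable[SiteCounts],
                    fallback: float = DEFAULT_FALLBACK_EPS) -> pd.DataFrame:
    """Assemble reduced sites into the table :func:`batch_call` consumes."""
    from .errors import site_error_rates

    rows = []
    for c in counts:
        rates = site_error_rates(c.quals_R, c.quals_A, fallback)
        rows.append((c.chrom, c.pos, c.ref, c.alt if c.alt else ".",
                     c.C, c.n_A, rates.eps_R, rates.eps_A))
    return pd.DataFrame(
        rows,
        columns=["chrom", "pos", "ref", "alt", "C", "n_A", "eps_R", "eps_A"],
    )


def call_pileup(source: Union[str, TextIO], N: int,
                prior: Union[Distribution, PriorSpec, None] = None,
                threshold: float = 0.9, min_depth: int = 5,
                max_depth: int = 40, offset: int = 33,
                return_posteriors: bool = False) -> CallBatch:
    """Parse a pileup file and call every site within the depth window.

    Sites with reference base N and sites whose used depth falls outside
    [min_depth, max_depth] are dropped before calling.
    """
    if prior is None:
        prior = PriorSpec()

    def _reduced(handle):
        for site in iter_pileup(handle):
            if site.skip:
                continue
            c = reduce_to_counts(site, offset=offset)
            if min_depth <= c.C <= max_depth:
                yield c

    if isinstance(source, str):
        with open(source) as handle:
            frame = counts_to_frame(_reduced(handle))
    else:
        frame = counts_to_frame(_reduced(source))
    if frame.empty:
        return CallBatch(results=pd.DataFrame(columns=RESULT_COLUMNS),
                         posteriors=np.empty((0, 0)) if return_posteriors else None)
    return batch_call(frame, N, prior, threshold=threshold,
                      return_posteriors=return_posteriors)


def write_calls(batch: CallBatch, dest: Union[str, TextIO],
                full_posterior: bool = False) -> None:
    """Write per-site results as TSV with one '#'-prefixed header line.

    With ``full_posterior`` the 101 posterior masses are appended as
    columns named by their grid frequency.
    """
    df = batch.results.copy()
    df["called"] = df["called"].astype(int)
    columns = list(df.columns)
    if full_posterior:
        if batch.posteriors is None or batch.posteriors.size == 0 and len(df):
            raise ValueError("batch was produced without posteriors")
        n_grid = batch.posteriors.shape[1] if len(df) else 101
        grid = np.arange(n_grid) / (n_grid - 1)
        post_cols = [f"post_f{v:.2f}" for v in grid]
        post_df = pd.DataFrame(
            batch.posteriors if len(df) else np.empty((0, n_grid)),
            columns=post_cols, index=df.index)
        df = pd.concat([df, post_df], axis=1)
        columns += post_cols

    def _write(handle: TextIO) -> None:
        handle.write("#" + "\t".join(columns) + "\n")
        df.to_csv(handle, sep="\t", header=False, index=False,
                  float_format="%.6g")

    if isinstance(dest, str):
        with open(dest, "w") as handle:
            _write(handle)
    else:
        _write(dest)


def read_calls(source: Union[str, TextIO]) -> pd.DataFrame:
    """Read a calls TSV written by :func:`write_calls`."""
    def _read(handle: TextIO) -> pd.DataFrame:
        header = handle.readline()
        if not header.startswith("#"):
            raise ValueError("calls file lacks its '#' header line")
        names = header[1:].rstrip("\n").split("\t")
        df = pd.read_csv(handle, sep="\t", names=names)
        if "called" not in df.columns:
            raise ValueError("calls file lacks the 'called' column")
        df["called"] = df["called"].astype(bool)
        return df

    if isinstance(source, str):
        with open(source) as handle:
            return _read(handle)
    return _read(source)
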