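"""Synthetic pooled-sequencing experiments.

The generator replaces a full coalescent + read-simulation + alignment
pipeline with the pieces the pooled-calling benchmark actually depends on:

* **Population SNPs.**  Segregating sites are placed independently along a
  region of length L.  Their number is Poisson with the Watterson
  expectation ``theta * L * sum_{i=1}^{N-1} 1/i`` and each site's
  alternative-allele count ``k`` among the N pooled chromosomes follows
  the neutral sample spectrum P(k) ∝ 1/k.  Linkage, recombination and
  demography are not modelled: the power/FDR/SFS summaries depend only on
  the marginal site frequencies and depths.

* **Pooling.**  Reads at a site are drawn independently from the N
  chromosomes, either uniformly or with a skewed scheme in which half of
  the (diploid) individuals contribute 1.5x and the other half 0.5x.

* **Sequencing.**  Per-site depth is Poisson (default mean 20).  Each read
  gets a Phred quality drawn from a discrete profile emulating short-read
  Illumina base qualities, and with the Phred-implied probability the
  emitted base is replaced by a uniform choice among the other three.
  Reads sit at their true positions; no aligner is simulated.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, TextIO, Union

import numpy as np
import pandas as pd

from .calling import class_rates_batch

__all__ = [
    "BASES",
    "DEFAULT_QUALITY_PROFILE",
    "PoolSimConfig",
    "TruthSite",
    "TruthTable",
    "ReadSet",
    "simulate_population",
    "simulate_reads",
    "simulate_experiment",
    "reads_to_frame",
    "write_pileup",
    "write_truth",
    "read_truth",
]

BASES = np.array(list("ACGT"))

#: Discrete Phred-score profile standing in for short-read Illumina base
#: qualities (mean per-base error ~1.2e-3).
DEFAULT_QUALITY_PROFILE: dict[int, float] = {
    20: 0.05, 25: 0.10, 30: 0.25, 35: 0.30, 40: 0.30,
}


@dataclass(frozen=True)
class PoolSimConfig:
    """Parameters of one pooled-sequencing simulation."""

    L: int = 200_000
    N: int = 50
    theta: float = 0.0005
    mean_depth: float = 20.0
    uneven: bool = False
    quality_profile: tuple[tuple[int, float], ...] = tuple(
        sorted(DEFAULT_QUALITY_PROFILE.items()))
    seed: int = 0
    chrom: str = "sim1"

    def __post_init__(self):
        if isinstance(self.quality_profile, dict):
            object.__setattr__(self, "quality_profile",
                               tuple(sorted(self.quality_profile.items())))
        if self.L < 1:
            raise ValueError("region length L must be >= 1")
        if self.N < 2:
            raise ValueError("pool must contain N >= 2 chromosomes")
        if self.uneven and self.N % 2 != 0:
            raise ValueError("uneven pooling needs an even number of "
                             "chromosomes (whole diploid individuals)")
        if self.theta < 0:
            raise ValueError("theta must be >= 0")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be > 0")
        total = sum(w for _, w in self.quality_profile)
        if not np.isclose(total, 1.0):
            raise ValueError("quality profile weights must sum to 1")

    @property
    def n_individuals(self) -> int:
        return self.N // 2

    def chromosome_weights(self) -> np.ndarray:
        """Relative sampling weight of each chromosome in the pool.

        Even pooling: all ones.  Uneven: half of the individuals weighted
        1.5 and half 0.5 (both chromosomes of an individual share its
        weight; with an odd individual count the middle one keeps 1.0).
        """
        if not self.uneven:
            return np.ones(self.N)
        n_ind = self.n_individuals
        ind_w = np.empty(n_ind)
        half = n_ind // 2
        ind_w[:half] = 1.5
        ind_w[n_ind - half:] = 0.5
        if n_ind % 2 == 1:
            ind_w[half] = 1.0
        return np.repeat(ind_w, 2)


@dataclass(frozen=True)
class TruthSite:
    """One segregating site of the pooled sample (1 <= k <= N-1)."""

    pos: int
    ref: str
    alt: str
    k: int


@dataclass
class TruthTable:
    """Population truth: reference sequence plus segregating sites."""

    config: PoolSimConfig
    positions: np.ndarray        # 1-based, sorted, unique
    k: np.ndarray                # alternative-allele counts, 1..N-1
    alt_codes: np.ndarray        # 0..3 per site
    ref_codes: Optional[np.ndarray]  # 0..3 per position, or None when loaded

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    @property
    def sites(self) -> list[TruthSite]:
        ref = self.site_ref_bases()
        return [
            TruthSite(int(p), r, str(BASES[a]), int(kk))
            for p, r, a, kk in zip(self.positions, ref, self.alt_codes, self.k)
        ]

    def site_ref_bases(self) -> np.ndarray:
        if self.ref_codes is None:
            return self._loaded_ref
        return BASES[self.ref_codes[self.positions - 1]]

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "pos": self.positions.astype(int),
            "ref": self.site_ref_bases(),
            "alt": BASES[self.alt_codes],
            "k": self.k.astype(int),
            "N": self.config.N,
        })


@dataclass
class ReadSet:
    """Flattened reads of one simulated experiment.

    ``site_idx`` maps each read to its 0-based position index; ``depth``
    is the per-position read count (so reads for position ``i`` are the
    contiguous block given by the cumulative depths).
    """

    depth: np.ndarray      # (L,)
    site_idx: np.ndarray   # (total_reads,)
    base: np.ndarray       # 0..3 emitted base per read
    qual: np.ndarray       # integer Phred score per read
    forward: np.ndarray    # strand flag per read


def _population_rng(config: PoolSimConfig) -> np.random.Generator:
    return np.random.default_rng([config.seed, 0])


def _read_rng(config: PoolSimConfig) -> np.random.Generator:
    return np.random.default_rng([config.seed, 1])


def simulate_population(config: PoolSimConfig) -> TruthTable:
    """Draw the reference sequence and the segregating sites of the pool.

    The number of segregating sites is Poisson with mean
    ``theta * L * H_{N-1}`` and each count k is drawn with P(k) ∝ 1/k —
    the neutral sample frequency spectrum.
    """
    rng = _population_rng(config)
    ref_codes = rng.integers(0, 4, size=config.L, dtype=np.int8)
    i = np.arange(1, config.N)
    sfs = (1.0 / i) / np.sum(1.0 / i)
    expected = config.theta * config.L * np.sum(1.0 / i)
    n_sites = min(int(rng.poisson(expected)), config.L) if expected > 0 else 0
    positions = np.sort(rng.choice(config.L, size=n_sites, replace=False)) + 1
    k = rng.choice(i, size=n_sites, p=sfs)
    # alternative base uniform over the three non-reference bases
    alt_codes = (ref_codes[positions - 1]
                 + rng.integers(1, 4, size=n_sites)) % 4
    return TruthTable(config=config, positions=positions, k=k,
                      alt_codes=alt_codes.astype(np.int8),
                      ref_codes=ref_codes)


def simulate_reads(truth: TruthTable) -> ReadSet:
    """Sequence the pool: Poisson depth, weighted chromosome sampling,
    Phred-profiled qualities and substitution errors."""
    config = truth.config
    if truth.ref_codes is None:
        raise ValueError("cannot simulate reads from a truth table loaded "
                         "without its reference sequence")
    rng = _read_rng(config)
    L, N = config.L, config.N

    depth = rng.poisson(config.mean_depth, size=L)
    total = int(depth.sum())
    site_idx = np.repeat(np.arange(L, dtype=np.int64), depth)

    # probability that a read at each position samples an alt chromosome
    p_alt = np.zeros(L)
    weights = config.chromosome_weights()
    if truth.n_sites:
        if config.uneven:
            w_total = weights.sum()
            p_site = np.empty(truth.n_sites)
            for j, kk in enumerate(truth.k):
                carriers = rng.choice(N, size=int(kk), replace=False)
                p_site[j] = weights[carriers].sum() / w_total
        else:
            p_site = truth.k / N
        p_alt[truth.positions - 1] = p_site

    alt_of_site = np.zeros(L, dtype=np.int8)
    if truth.n_sites:
        alt_of_site[truth.positions - 1] = truth.alt_codes

    from_alt = rng.random(total) < p_alt[site_idx]
    base = truth.ref_codes[site_idx].astype(np.int8)
    base[from_alt] = alt_of_site[site_idx[from_alt]]

    levels = np.array([q for q, _ in config.quality_profile])
    probs = np.array([w for _, w in config.quality_profile])
    qual = rng.choice(levels, size=total, p=probs)
    err = rng.random(total) < 10.0 ** (-qual / 10.0)
    n_err = int(err.sum())
    base[err] = (base[err] + rng.integers(1, 4, size=n_err)) % 4

    forward = rng.random(total) < 0.5
    return ReadSet(depth=depth, site_idx=site_idx, base=base,
                   qual=qual.astype(np.int16), forward=forward)


def simulate_experiment(config: PoolSimConfig) -> tuple[TruthTable, ReadSet]:
    truth = simulate_population(config)
    return truth, simulate_reads(truth)


def reads_to_frame(truth: TruthTable, reads: ReadSet) -> pd.DataFrame:
    """Reduce simulated reads directly to the counts table consumed by
    :func:`poolmaf.calling.batch_call`.

    Equivalent to writing a pileup and parsing it back (the round trip is
    exercised in the test suite), but without the text detour.
    """
    config = truth.config
    L = config.L
    ref_codes = truth.ref_codes
    is_alt = reads.base != ref_codes[reads.site_idx]

    C = reads.depth.astype(np.int64)
    n_A = np.bincount(reads.site_idx[is_alt], minlength=L)

    err_prob = 10.0 ** (-reads.qual / 10.0)
    eps_r, eps_a = class_rates_batch(reads.site_idx, is_alt, err_prob, L)

    # most frequent non-reference base per site (tie -> lexicographic)
    alt_counts = np.zeros((L, 4), dtype=np.int32)
    for b in range(4):
        alt_counts[:, b] = np.bincount(
            reads.site_idx[reads.base == b], minlength=L)
    alt_counts[np.arange(L), ref_codes.astype(int)] = 0
    alt_code = np.argmax(alt_counts, axis=1)
    alt = np.where(n_A > 0, BASES[alt_code], ".")

    return pd.DataFrame({
        "chrom": config.chrom,
        "pos": np.arange(1, L + 1),
        "ref": BASES[ref_codes.astype(int)],
        "alt": alt,
        "C": C,
        "n_A": n_A,
        "eps_R": eps_r,
        "eps_A": eps_a,
    })


def write_pileup(truth: TruthTable, reads: ReadSet,
                 dest: Union[str, TextIO]) -> None:
    """Emit the simulated reads as 6-column samtools pileup text.

    Reference matches are encoded "."/"," by strand, mismatches as
    upper/lower-case letters, qualities as Phred+33 characters.  Empty
    sites get the samtools "*" placeholder columns.
    """
    config = truth.config
    ref_codes = truth.ref_codes
    ref_read = ref_codes[reads.site_idx]
    match = reads.base == ref_read

    base_char = np.empty(len(reads.base), dtype="U1")
    letters_f = BASES
    letters_r = np.array(list("acgt"))
    fwd = reads.forward
    base_char[match & fwd] = "."
    base_char[match & ~fwd] = ","
    mm_f = ~match & fwd
    mm_r = ~match & ~fwd
    base_char[mm_f] = letters_f[reads.base[mm_f].astype(int)]
    base_char[mm_r] = letters_r[reads.base[mm_r].astype(int)]
    qual_char = np.array([chr(33 + q) for q in range(94)])[
        np.clip(reads.qual, 0, 93)]

    offsets = np.concatenate([[0], np.cumsum(reads.depth)]).astype(int)
    ref_bases = BASES[ref_codes.astype(int)]
    chrom = config.chrom

    def _write(handle: TextIO) -> None:
        for i in range(config.L):
            lo, hi = offsets[i], offsets[i + 1]
            if lo == hi:
                handle.write(f"{chrom}\t{i + 1}\t{ref_bases[i]}\t0\t*\t*\n")
            else:
                handle.write(
                    f"{chrom}\t{i + 1}\t{ref_bases[i]}\t{hi - lo}\t"
                    f"{''.join(base_char[lo:hi])}\t"
                    f"{''.join(qual_char[lo:hi])}\n")

    if isinstance(dest, str):
        with open(dest, "w") as handle:
            _write(handle)
    else:
        _write(dest)


def write_truth(truth: TruthTable, dest: Union[str, TextIO]) -> None:
    """Truth table as TSV with the config echoed in '##' header lines."""
    config = truth.config
    meta = (
        f"## poolmaf-truth chrom={config.chrom} L={config.L} N={config.N} "
        f"theta={config.theta} mean_depth={config.mean_depth} "
        f"uneven={int(config.uneven)} seed={config.seed}\n"
    )

    def _write(handle: TextIO) -> None:
        handle.write(meta)
        truth.frame().to_csv(handle, sep="\t", index=False)

    if isinstance(dest, str):
        with open(dest, "w") as handle:
            _write(handle)
    else:
        _write(dest)


def read_truth(source: Union[str, TextIO]) -> TruthTable:
    """Load a truth TSV written by :func:`write_truth`.

    The reference sequence is not stored in the TSV, so the returned table
    supports evaluation but not re-simulation.
    """
    def _read(handle: TextIO) -> TruthTable:
        meta: dict[str, str] = {}
        pos = handle.tell()
        line = handle.readline()
        while line.startswith("##"):
            for tok in line[2:].split():
                if "=" in tok:
                    key, _, val = tok.partition("=")
                    meta[key] = val
            pos = handle.tell()
            line = handle.readline()
        handle.seek(pos)
        df = pd.read_csv(handle, sep="\t")
        n_pool = int(meta.get("N", df["N"].iloc[0] if len(df) else 2))
        config = PoolSimConfig(
            L=int(meta.get("L", max(df["pos"].max() if len(df) else 1, 1))),
            N=n_pool,
            theta=float(meta.get("theta", 0.0005)),
            mean_depth=float(meta.get("mean_depth", 20.0)),
            uneven=bool(int(meta.get("uneven", 0))),
            seed=int(meta.get("seed", 0)),
            chrom=meta.get("chrom", "sim1"),
        )
        base_index = {b: i for i, b in enumerate("ACGT")}
        table = TruthTable(
            config=config,
            positions=df["pos"].to_numpy(dtype=np.int64),
            k=df["k"].to_numpy(dtype=np.int64),
            alt_codes=np.array([base_index[b] for b in df["alt"]],
                               dtype=np.int8),
            ref_codes=None,
        )
        table._loaded_ref = df["ref"].to_numpy(dtype="U1")
        return table

    if isinstance(source, str):
        with open(source) as handle:
            return _read(handle)
    return _read(source)
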