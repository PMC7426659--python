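"""Relative and quantitative microbiome profiling normalizations.

Microbiome sequencing yields compositional data: each sample's read counts
sum to an arbitrary sequencing depth, so only relative information survives.
Relative microbiome profiling (RMP) rarefies every sample to a common read
count and reports proportions.  Quantitative microbiome profiling (QMP)
instead anchors sequencing data to an externally measured microbial load
(cells per gram of sample): read counts are first corrected for 16S rRNA
gene copy number (``k_t`` copies per genome for taxon ``t``), then rarefied
to an even *sampling depth* -- corrected reads per cell,
``SD_s = D_s / L_s`` -- and finally rescaled so that each sample's profile
sums to its measured load ``L_s``.

Two quantitative variants share the same arithmetic: QMP-PMA applies it to
sequencing libraries prepared after propidium-monoazide treatment (intact
cells only), and QMP-qPCR derives the per-sample load from a qPCR
measurement of total 16S copies per gram divided by the sample's average
copy number per cell (:func:`avg_copies_per_cell`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

ROUNDING_MODES = ("half_away", "floor", "stochastic")


# ---------------------------------------------------------------------------
# containers


@dataclass
class TaxonCountTable:
    """Integer taxon-by-sample read count matrix ``C_st``.

    Taxa are rows, samples are columns.  Per-sample raw depth
    ``R_s = sum_t C_st`` is exposed as :attr:`depths`.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        if not isinstance(self.counts, pd.DataFrame):
            self.counts = pd.DataFrame(self.counts)
        if self.counts.empty:
            raise ValueError("count table is empty")
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate taxon ids in count table")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate sample ids in count table")
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            if not np.allclose(values, np.round(values), atol=0):
                raise TypeError("count table contains non-integer values")
            self.counts = self.counts.astype(np.int64)
            values = self.counts.to_numpy()
        if (values < 0).any():
            raise ValueError("count table contains negative values")

    @property
    def taxa(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    @property
    def depths(self) -> pd.Series:
        """Raw per-sample sequencing depth ``R_s``."""
        return self.counts.sum(axis=0)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"TaxonCountTable({self.counts.shape[0]} taxa x "
            f"{self.counts.shape[1]} samples)"
        )


@dataclass
class CopyNumberTable:
    """Per-taxon 16S rRNA gene copy numbers ``k_t`` (copies per genome).

    ``default`` is applied to taxa absent from the table; the defaulted
    taxa are logged.  All copy numbers must be >= 1.
    """

    copy_numbers: pd.Series
    default: float | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.copy_numbers, pd.Series):
            self.copy_numbers = pd.Series(self.copy_numbers, dtype=float)
        self.copy_numbers = self.copy_numbers.astype(float)
        if self.copy_numbers.index.has_duplicates:
            raise ValueError("duplicate taxon ids in copy-number table")
        if (self.copy_numbers < 1).any():
            bad = self.copy_numbers[self.copy_numbers < 1].index.tolist()
            raise ValueError(f"copy numbers below 1 for taxa: {bad}")
        if self.default is not None and self.default < 1:
            raise ValueError("default copy number must be >= 1")

    def resolve(self, taxa: Iterable[str]) -> pd.Series:
        """Copy numbers for ``taxa``, falling back to ``default``.

        Raises ``KeyError`` listing unresolvable taxa when no default is set.
        """
        taxa = pd.Index(taxa)
        out = self.copy_numbers.reindex(taxa)
        missing = taxa[out.isna()]
        if len(missing):
            if self.default is None:
                raise KeyError(
                    f"no copy number and no default for taxa: {list(missing)}"
                )
            log.warning(
                "using default copy number %.3f for %d taxa: %s",
                self.default,
                len(missing),
                list(missing),
            )
            out[missing] = self.default
        return out


@dataclass
class QuantProfile:
    """A profiled abundance matrix with its normalization provenance.

    ``abundances`` holds proportions for RMP and cells/gram for the
    QMP-family methods.  ``sampling_depth`` is the realized number of reads
    retained per sample after rarefaction; ``loads`` is the per-sample
    microbial load the profile was anchored to (``None`` for RMP).
    ``rarefied`` retains the integer rarefied count table (used e.g. for
    Dirichlet-multinomial enterotyping downstream).
    """

    method: str
    abundances: pd.DataFrame
    sampling_depth: pd.Series
    loads: pd.Series | None = None
    seed: int | None = None
    rarefied: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        colsums = self.abundances.sum(axis=0)
        if self.loads is None:
            if not np.allclose(colsums.to_numpy(), 1.0, atol=1e-9):
                raise ValueError("relative profile columns must sum to 1")
        else:
            loads = self.loads.reindex(self.abundances.columns)
            rel = np.abs(colsums.to_numpy() - loads.to_numpy()) / loads.to_numpy()
            if (rel > 1e-6).any():
                raise ValueError(
                    "quantitative profile columns must sum to the supplied loads"
                )

    @property
    def samples(self) -> pd.Index:
        return self.abundances.columns

    @property
    def taxa(self) -> pd.Index:
        return self.abundances.index

    def relative(self) -> pd.DataFrame:
        """Row-stochastic view: per-sample proportions."""
        return self.abundances / self.abundances.sum(axis=0)


# ---------------------------------------------------------------------------
# helpers


def _as_table(counts) -> TaxonCountTable:
    if isinstance(counts, TaxonCountTable):
        return counts
    return TaxonCountTable(pd.DataFrame(counts))


def _as_copy_table(copy_numbers) -> CopyNumberTable:
    if isinstance(copy_numbers, CopyNumberTable):
        return copy_numbers
    return CopyNumberTable(pd.Series(copy_numbers, dtype=float))


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Derive ``n`` independent deterministic sub-streams from one seed."""
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(child) for child in ss.spawn(n)]


# ---------------------------------------------------------------------------
# operations


def copy_number_correct(
    counts,
    copy_numbers,
    rounding: str = "half_away",
    seed: int | np.random.Generator | None = None,
) -> tuple[TaxonCountTable, pd.Series]:
    """Divide counts by per-taxon 16S copy numbers and re-integerize.

    Returns the corrected integer table ``C'_st = round(C_st / k_t)`` and
    the corrected per-sample depths ``D_s = sum_t C'_st``.  Rounding is half
    away from zero by default; ``floor`` and ``stochastic`` (probabilistic
    rounding, requires ``seed``) are available.  Taxa whose nonzero counts
    collapse to zero are reported via a logged warning.
    """
    table = _as_table(counts)
    ktab = _as_copy_table(copy_numbers)
    if rounding not in ROUNDING_MODES:
        raise ValueError(f"rounding must be one of {ROUNDING_MODES}")
    k = ktab.resolve(table.taxa).to_numpy()[:, None]
    raw = table.counts.to_numpy(dtype=float) / k
    if rounding == "half_away":
        corrected = np.floor(raw + 0.5)
    elif rounding == "floor":
        corrected = np.floor(raw)
    else:
        rng = _rng(seed)
        base = np.floor(raw)
        corrected = base + (rng.random(raw.shape) < (raw - base))
    corrected = corrected.astype(np.int64)
    lost = ((table.counts.to_numpy() > 0) & (corrected == 0)).any(axis=1)
    if lost.any():
        log.warning(
            "copy-number correction zeroed nonzero counts for taxa: %s",
            list(table.taxa[lost]),
        )
    out = TaxonCountTable(
        pd.DataFrame(corrected, index=table.taxa, columns=table.samples)
    )
    return out, out.depths


def rarefy_counts(row, n: int, seed: int | np.random.Generator | None = None) -> np.ndarray:
    """Subsample a count vector to ``n`` reads without replacement.

    Draws from the multivariate hypergeometric distribution, i.e. the exact
    distribution of randomly selecting ``n`` of the observed reads.
    """
    row = np.asarray(row)
    if not np.issubdtype(row.dtype, np.integer):
        if not np.allclose(row, np.round(row), atol=0):
            raise TypeError("rarefaction requires integer counts")
        row = row.astype(np.int64)
    if (row < 0).any():
        raise ValueError("negative counts")
    total = int(row.sum())
    if n < 0 or n > total:
        raise ValueError(f"rarefaction target {n} outside [0, {total}]")
    rng = _rng(seed)
    return rng.multivariate_hypergeometric(row, int(n)).astype(np.int64)


def rmp_profile(
    counts,
    target_depth: int | None = None,
    seed: int = 0,
    on_shallow: str = "error",
) -> QuantProfile:
    """Relative microbiome profiling: rarefy to an even read count.

    Every sample is subsampled to ``target_depth`` reads (default: the
    minimum depth across samples) and divided by the target, yielding
    proportions.  Samples below the target either raise (``on_shallow=
    'error'``, listing the offenders) or are dropped with a warning
    (``'drop'``).
    """
    table = _as_table(counts)
    depths = table.depths
    if target_depth is None:
        target_depth = int(depths.min())
    if target_depth < 0:
        raise ValueError("target depth must be >= 0")
    shallow = depths.index[depths < target_depth]
    if len(shallow):
        if on_shallow == "drop":
            log.warning("dropping samples below target depth: %s", list(shallow))
            table = TaxonCountTable(table.counts.drop(columns=shallow))
        else:
            raise ValueError(
                f"samples below target depth {target_depth}: {list(shallow)}"
            )
    rngs = _spawn_rngs(seed, len(table.samples))
    rarefied = np.column_stack(
        [
            rarefy_counts(table.counts[s].to_numpy(), target_depth, rng)
            for s, rng in zip(table.samples, rngs)
        ]
    )
    rarefied_df = pd.DataFrame(rarefied, index=table.taxa, columns=table.samples)
    abundances = rarefied_df / float(target_depth)
    depth_series = pd.Series(target_depth, index=table.samples, dtype=np.int64)
    return QuantProfile(
        method="RMP",
        abundances=abundances,
        sampling_depth=depth_series,
        loads=None,
        seed=seed,
        rarefied=rarefied_df,
    )


def qmp_profile(
    counts,
    copy_numbers,
    loads,
    seed: int = 0,
    rounding: str = "half_away",
    method_tag: str = "QMP",
) -> QuantProfile:
    """Cell-count-anchored quantitative microbiome profiling.

    Steps: (1) copy-number correct the counts; (2) compute per-sample
    sampling depths ``SD_s = D_s / L_s`` and their minimum ``SD_min``;
    (3) rarefy each sample to ``n_s = floor(SD_min * L_s)`` corrected reads
    (guaranteed feasible); (4) rescale to cells/gram as
    ``abundance_st = rarefied_st / n_s * L_s``.  Each output column sums to
    its load exactly, and realized sampling depths ``n_s / L_s`` agree
    across samples to within ``1 / L_s``.
    """
    table = _as_table(counts)
    if not isinstance(loads, pd.Series):
        loads = pd.Series(loads)
    loads = loads.astype(float)
    missing = table.samples.difference(loads.index)
    if len(missing):
        raise ValueError(f"missing loads for samples: {list(missing)}")
    loads = loads.reindex(table.samples)
    if (loads <= 0).any():
        raise ValueError("loads must be positive")

    corrected, depths = copy_number_correct(table, copy_numbers, rounding, seed)
    sd = depths.to_numpy(dtype=float) / loads.to_numpy()
    sd_min = sd.min()
    targets = np.floor(sd_min * loads.to_numpy()).astype(np.int64)
    targets = np.minimum(targets, depths.to_numpy())  # guard float roundoff
    if (targets <= 0).any():
        bad = list(table.samples[targets <= 0])
        raise ValueError(f"even sampling depth leaves zero reads for: {bad}")

    rngs = _spawn_rngs(seed, len(table.samples))
    rarefied = np.column_stack(
        [
            rarefy_counts(corrected.counts[s].to_numpy(), int(t), rng)
            for s, t, rng in zip(table.samples, targets, rngs)
        ]
    )
    rarefied_df = pd.DataFrame(rarefied, index=table.taxa, columns=table.samples)
    abundances = rarefied_df / targets.astype(float) * loads.to_numpy()
    return QuantProfile(
        method=method_tag,
        abundances=abundances,
        sampling_depth=pd.Series(targets, index=table.samples),
        loads=loads,
        seed=seed,
        rarefied=rarefied_df,
    )


def avg_copies_per_cell(counts, copy_numbers, rounding: str = "half_away") -> pd.Series:
    """Per-sample average 16S copies per cell ``A_s = R_s / D_s``.

    ``R_s`` is the raw read count and ``D_s`` the copy-number-corrected
    count, so ``A_s`` is the read-weighted mean copy number of sample ``s``.
    """
    table = _as_table(counts)
    _, depths = copy_number_correct(table, copy_numbers, rounding)
    if (depths <= 0).any():
        bad = list(depths.index[depths <= 0])
        raise ValueError(f"zero corrected depth for samples: {bad}")
    return table.depths.astype(float) / depths.astype(float)


def qpcr_copies_to_load(copies_per_gram, avg_copies) -> pd.Series:
    """Convert total 16S copies/gram into cells/gram: ``L_s = Q_s / A_s``."""
    if not isinstance(copies_per_gram, pd.Series):
        copies_per_gram = pd.Series(copies_per_gram)
    if not isinstance(avg_copies, pd.Series):
        avg_copies = pd.Series(avg_copies, index=copies_per_gram.index)
    avg_copies = avg_copies.reindex(copies_per_gram.index)
    if avg_copies.isna().any() or (avg_copies <= 0).any():
        raise ValueError("average copy number must be positive for every sample")
    return copies_per_gram.astype(float) / avg_copies.astype(float)


def qmp_qpcr_profile(
    counts,
    copy_numbers,
    copies_per_gram,
    seed: int = 0,
    rounding: str = "half_away",
) -> QuantProfile:
    """qPCR-anchored QMP: derive loads from total 16S copies/gram.

    The per-sample load is the qPCR copy measurement divided by the
    sample's average copy number per cell (estimated from the sequencing
    data); the standard QMP normalization is then applied unchanged.
    """
    table = _as_table(counts)
    avg = avg_copies_per_cell(table, copy_numbers, rounding)
    loads = qpcr_copies_to_load(copies_per_gram, avg)
    return qmp_profile(
        table, copy_numbers, loads, seed=seed, rounding=rounding,
        method_tag="QMP-qPCR",
    )
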