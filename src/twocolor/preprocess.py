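"""Reading, quantile normalization and intensity filtering of channel data.

The analysis treats the two dye channels of every array as separate
observations, so an experiment with *n* arrays yields a probes x 2n matrix
of intensities.  Raw intensities are quantile-normalized with all channels
pooled (forcing every channel onto the common rank-wise mean distribution,
which makes channels exchangeable — a prerequisite of the intensity-based
analysis), then log2-transformed.  No background correction is applied.

Probes expressed near the noise floor are removed with a mean-intensity
filter: only probes whose average log2 intensity A across *all* channels
exceeds a threshold (default 7) are retained.  The filter is global, so the
per-probe sample size is identical for every retained probe.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .design import ChannelKey

logger = logging.getLogger(__name__)

DIALECT_WIDE_TSV = "wide-tsv"
DIALECT_AGILENT_FE = "agilent-fe"


@dataclass
class ExpressionMatrix:
    """Probes x channels intensity matrix with channel metadata.

    ``log2`` records whether ``values`` are on the log2 scale; raw matrices
    straight from :func:`read_channels` are not, matrices returned by
    :func:`quantile_normalize` are.
    """

    probe_ids: np.ndarray
    channels: list[ChannelKey]
    values: np.ndarray
    log2: bool = False

    def __post_init__(self) -> None:
        self.probe_ids = np.asarray(self.probe_ids, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.probe_ids), len(self.channels)):
            raise ValueError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.probe_ids)} probes x {len(self.channels)} channels"
            )
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("duplicate channels in matrix")
        if len(set(self.probe_ids)) != len(self.probe_ids):
            raise ValueError("duplicate probe identifiers in matrix")

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def a_values(self) -> np.ndarray:
        """Per-probe mean intensity A (row mean), recomputed on access."""
        return self.values.mean(axis=1)

    def channel_vector(self, channel: ChannelKey) -> np.ndarray:
        return self.values[:, self.channels.index(channel)]

    def subset_channels(self, channels: Sequence[ChannelKey]) -> "ExpressionMatrix":
        idx = [self.channels.index(c) for c in channels]
        return ExpressionMatrix(
            self.probe_ids.copy(), list(channels), self.values[:, idx], self.log2
        )

    def subset_probes(self, mask: np.ndarray) -> "ExpressionMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            return ExpressionMatrix(
                self.probe_ids[mask], list(self.channels), self.values[mask], self.log2
            )
        raise TypeError("subset_probes expects a boolean mask")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=pd.Index(self.probe_ids, name="probe_id"),
            columns=[str(c) for c in self.channels],
        )

    def write_tsv(self, path, provenance: str | None = None) -> None:
        """Write as wide TSV; an optional provenance note goes in a comment."""
        with open(path, "w") as fh:
            if provenance:
                fh.write(f"# {provenance}\n")
            # %.17g guarantees an exact binary round trip through text
            self.to_frame().to_csv(fh, sep="\t", float_format="%.17g")


def read_channels(
    source,
    dialect: str = DIALECT_WIDE_TSV,
    *,
    probe_col: str = "ProbeName",
    green_col: str = "gMedianSignal",
    red_col: str = "rMedianSignal",
) -> ExpressionMatrix:
    """Read two-channel intensity data into a raw-scale matrix.

    Parameters
    ----------
    source
        For ``wide-tsv``: a path to a tab-delimited table whose first column
        holds probe IDs and whose remaining columns are named ``array:dye``.
        For ``agilent-fe``: a mapping ``{array_id: path}`` (or a sequence of
        paths, in which case the file stem is the array id) of per-array
        tab-delimited feature tables carrying a probe-ID column and one
        signal column per dye.
    dialect
        ``"wide-tsv"`` or ``"agilent-fe"``.
    probe_col, green_col, red_col
        Column names for the ``agilent-fe`` dialect; the defaults match
        Feature Extraction median-signal exports.  Green maps to Cy3, red
        to Cy5.

    Probes are aligned by ID across arrays; probes absent from any array are
    dropped (logged).  No background subtraction is performed.
    """
    if dialect == DIALECT_WIDE_TSV:
        return _read_wide_tsv(source)
    if dialect == DIALECT_AGILENT_FE:
        return _read_agilent_fe(source, probe_col, green_col, red_col)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_wide_tsv(source) -> ExpressionMatrix:
    frame = pd.read_csv(source, sep="\t", comment="#", index_col=0,
                        float_precision="round_trip")
    if frame.shape[1] == 0:
        raise ValueError("wide TSV has no channel columns")
    channels = [ChannelKey.parse(str(c)) for c in frame.columns]
    values = frame.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("non-numeric or missing signal values in wide TSV")
    return ExpressionMatrix(frame.index.to_numpy(dtype=object), channels, values, log2=False)


def _read_agilent_fe(source, probe_col, green_col, red_col) -> ExpressionMatrix:
    if isinstance(source, Mapping):
        items = list(source.items())
    else:
        items = [(Path(p).stem, p) for p in source]
    if not items:
        raise ValueError("no per-array files given")

    per_array: list[tuple[str, pd.DataFrame]] = []
    for array_id, path in items:
        table = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
        for col in (probe_col, green_col, red_col):
            if col not in table.columns:
                raise ValueError(f"file for array {array_id} lacks column {col!r}")
        table = table[[probe_col, green_col, red_col]].copy()
        n_dup = table[probe_col].duplicated().sum()
        if n_dup:
            logger.warning("array %s: %d duplicate probe rows, keeping first", array_id, n_dup)
            table = table.drop_duplicates(subset=probe_col, keep="first")
        table = table.set_index(probe_col)
        per_array.append((str(array_id), table))

    common = per_array[0][1].index
    union = per_array[0][1].index
    for _, table in per_array[1:]:
        common = common.intersection(table.index)
        union = union.union(table.index)
    if len(common) == 0:
        raise ValueError("no probes in common across arrays")
    # preserve the first file's probe order
    order = [p for p in per_array[0][1].index if p in set(common)]
    n_dropped = len(union) - len(order)
    if n_dropped > 0:
        logger.warning("%d probes dropped (absent from at least one array)", n_dropped)

    channels: list[ChannelKey] = []
    columns: list[np.ndarray] = []
    for array_id, table in per_array:
        aligned = table.loc[order]
        channels.append(ChannelKey(array_id, "Cy3"))
        columns.append(aligned[green_col].to_numpy(dtype=float))
        channels.append(ChannelKey(array_id, "Cy5"))
        columns.append(aligned[red_col].to_numpy(dtype=float))
    values = np.column_stack(columns)
    if not np.isfinite(values).all():
        raise ValueError("non-numeric signal values in per-array files")
    return ExpressionMatrix(np.asarray(order, dtype=object), channels, values, log2=False)


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalize all channels jointly, then log2-transform.

    Every channel is mapped onto the pooled reference distribution (the mean
    of the per-rank sorted values across channels).  Tied values receive the
    mean of the reference values at their tied ranks, so dye-swapped
    duplicates normalize symmetrically.  The input must be raw-scale and
    strictly positive; the output is log2.
    """
    if m.log2:
        raise ValueError("matrix is already log2-scale; quantile_normalize expects raw data")
    for j, ch in enumerate(m.channels):
        if not (m.values[:, j] > 0).all():
            raise ValueError(f"nonpositive intensities in channel {ch}")

    n = m.n_probes
    sorted_cols = np.sort(m.values, axis=0)
    reference = sorted_cols.mean(axis=1)
    out = np.empty_like(m.values)
    positions = np.arange(1, n + 1, dtype=float)
    for j in range(m.n_channels):
        ranks = rankdata(m.values[:, j], method="average")
        out[:, j] = np.interp(ranks, positions, reference)
    return ExpressionMatrix(m.probe_ids.copy(), list(m.channels), np.log2(out), log2=True)


def filter_by_mean_intensity(m: ExpressionMatrix, threshold: float = 7.0) -> ExpressionMatrix:
    """Keep probes whose mean log2 intensity across all channels exceeds ``threshold``.

    The inequality is strict (A > threshold).  Removal is global: a probe is
    dropped from every channel, so per-probe sample sizes remain equal.
    """
    if not m.log2:
        raise ValueError("filter_by_mean_intensity expects a log2-scale matrix")
    if np.isnan(threshold):
        raise ValueError("threshold must not be NaN")
    mask = m.a_values > threshold
    logger.info("mean-intensity filter A > %g: %d of %d probes retained",
                threshold, int(mask.sum()), m.n_probes)
    return m.subset_probes(mask)
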