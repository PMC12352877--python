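"""Signal tracks and TSS-window binning.

A :class:`SignalTrack` abstracts over the ways per-feature sequencing signal
arrives: an in-memory event list, a coordinate-sorted indexed BAM, a bedGraph,
or a bigWig.  Two counting modes exist:

``event-start``
    Each alignment/event contributes 1 to the bin containing its 5'-most
    genomic coordinate (the natural mode for BAM and event lists).
``base-coverage``
    Each bin holds the sum of per-base coverage values over its bases (the
    natural mode for bedGraph/bigWig).

:func:`bin_counts` turns a track restricted to a gene's window into the
fixed-length bin vector, reversing bin order for "−" strand genes when the
window is gene-oriented.
"""

from __future__ import annotations

from abc import ABC, abstractmethod
from typing import Mapping, Sequence

import numpy as np

from .annotation import BinSpec, Window


class ChromosomeMissingError(KeyError):
    """A queried chromosome is absent from the track."""

    def __init__(self, chrom: str, source: str = ""):
        suffix = f" in {source}" if source else ""
        super().__init__(f"chromosome {chrom!r} not present{suffix}")
        self.chrom = chrom


class SignalTrack(ABC):
    """Queryable signal source for one feature."""

    #: one of "event-start" | "base-coverage"
    mode: str = "event-start"

    def __init__(self, feature: str):
        self.feature = feature

    @abstractmethod
    def events_in(self, chrom: str, start: int, end: int) -> np.ndarray:
        """0-based positions of event 5' ends within [start, end)."""

    def coverage(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-base coverage over [start, end); positions before base 0 are zero."""
        raise NotImplementedError(f"{type(self).__name__} has no base-coverage mode")


class InMemoryEventTrack(SignalTrack):
    """Event positions held in memory, keyed by chromosome (mainly for tests
    and simulation output)."""

    mode = "event-start"

    def __init__(self, feature: str, events: Mapping[str, Sequence[int]]):
        super().__init__(feature)
        self._events = {c: np.asarray(p, dtype=np.int64) for c, p in events.items()}

    def events_in(self, chrom: str, start: int, end: int) -> np.ndarray:
        if chrom not in self._events:
            raise ChromosomeMissingError(chrom, "in-memory track")
        pos = self._events[chrom]
        return pos[(pos >= start) & (pos < end)]


class BamTrack(SignalTrack):
    """Alignments from a coordinate-sorted indexed BAM/SAM; each read counts
    once at its 5'-most coordinate (reference_start for forward reads,
    reference_end − 1 for reverse reads)."""

    mode = "event-start"

    def __init__(self, feature: str, path: str):
        import pysam

        super().__init__(feature)
        self.path = path
        self._af = pysam.AlignmentFile(path)

    def events_in(self, chrom: str, start: int, end: int) -> np.ndarray:
        if chrom not in self._af.references:
            raise ChromosomeMissingError(chrom, self.path)
        out = []
        for read in self._af.fetch(chrom, max(start, 0), end):
            if read.is_unmapped:
                continue
            five_prime = (read.reference_end - 1) if read.is_reverse else read.reference_start
            if start <= five_prime < end:
                out.append(five_prime)
        return np.asarray(out, dtype=np.int64)


class BigWigTrack(SignalTrack):
    """Per-base coverage from a bigWig file."""

    mode = "base-coverage"

    def __init__(self, feature: str, path: str):
        import pyBigWig

        super().__init__(feature)
        self.path = path
        self._bw = pyBigWig.open(path)

    def events_in(self, chrom: str, start: int, end: int) -> np.ndarray:
        raise NotImplementedError("bigWig tracks are base-coverage only")

    def coverage(self, chrom: str, start: int, end: int) -> np.ndarray:
        if chrom not in self._bw.chroms():
            raise ChromosomeMissingError(chrom, self.path)
        out = np.zeros(end - start, dtype=float)
        q_start = max(start, 0)
        q_end = min(end, self._bw.chroms()[chrom])
        if q_end > q_start:
            vals = np.nan_to_num(
                np.asarray(self._bw.values(chrom, q_start, q_end), dtype=float)
            )
            out[q_start - start : q_end - start] = vals
        return out


class BedGraphTrack(SignalTrack):
    """Per-base coverage reconstructed from a bedGraph (chrom, start, end, value)."""

    mode = "base-coverage"

    def __init__(self, feature: str, path_or_buffer):
        import pandas as pd

        super().__init__(feature)
        df = pd.read_csv(
            path_or_buffer,
            sep=r"\s+",
            comment="#",
            header=None,
            names=["chrom", "start", "end", "value"],
            dtype={"chrom": str},
        )
        df = df[~df["chrom"].astype(str).str.startswith(("track", "browser"))]
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, sub in df.groupby("chrom", sort=False):
            sub = sub.sort_values("start")
            self._by_chrom[str(chrom)] = (
                sub["start"].to_numpy(np.int64),
                sub["end"].to_numpy(np.int64),
                sub["value"].to_numpy(float),
            )

    def events_in(self, chrom: str, start: int, end: int) -> np.ndarray:
        raise NotImplementedError("bedGraph tracks are base-coverage only")

    def coverage(self, chrom: str, start: int, end: int) -> np.ndarray:
        if chrom not in self._by_chrom:
            raise ChromosomeMissingError(chrom, "bedGraph track")
        starts, ends, values = self._by_chrom[chrom]
        out = np.zeros(end - start, dtype=float)
        lo = int(np.searchsorted(ends, start, side="right"))
        for s, e, v in zip(starts[lo:], ends[lo:], values[lo:]):
            if s >= end:
                break
            a, b = max(s, start, 0), min(e, end)
            if b > a:
                out[a - start : b - start] = v
        return out


def open_track(feature: str, path: str) -> SignalTrack:
    """Open a track file, dispatching on extension (.bam/.sam, .bw/.bigwig,
    .bedgraph/.bg)."""
    low = path.lower()
    if low.endswith((".bam", ".sam", ".cram")):
        return BamTrack(feature, path)
    if low.endswith((".bw", ".bigwig")):
        return BigWigTrack(feature, path)
    if low.endswith((".bedgraph", ".bg", ".bedgraph.txt")):
        return BedGraphTrack(feature, path)
    raise ValueError(f"cannot infer track format from {path!r}")


def bin_counts(track: SignalTrack, window: Window, spec: BinSpec | None = None) -> np.ndarray:
    """Bin a track's signal over a TSS window into ``spec.n_bins`` values.

    In event-start mode each event whose 5'-most coordinate lies in bin *b*
    increments bin *b* by one, so the vector sum equals the number of
    in-window events exactly.  In base-coverage mode bin *b* holds the sum of
    per-base coverage over its bases.  For "−" strand genes with an oriented
    window the vector is reversed so bins run 5'→3' of the gene.
    """
    spec = spec or BinSpec()
    if window.end - window.start != spec.window_length:
        raise ValueError(
            f"window length {window.end - window.start} does not match "
            f"spec window of {spec.window_length} bases"
        )
    if track.mode == "event-start":
        pos = track.events_in(window.chrom, window.start, window.end)
        idx = (np.asarray(pos, dtype=np.int64) - window.start) // spec.bin_width
        counts = np.bincount(idx, minlength=spec.n_bins).astype(float)
    elif track.mode == "base-coverage":
        cov = np.asarray(track.coverage(window.chrom, window.start, window.end), dtype=float)
        if cov.shape[0] != spec.window_length:
            raise ValueError("coverage length does not match window length")
        if np.any(cov < 0):
            raise ValueError(f"negative coverage value in {track.feature} track")
        counts = cov.reshape(spec.n_bins, spec.bin_width).sum(axis=1)
    else:
        raise ValueError(f"unknown counting mode {track.mode!r}")
    if window.oriented and window.strand == "-":
        counts = counts[::-1]
    return counts
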