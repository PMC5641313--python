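"""Epigenomic signal tracks: binning to model resolution and correlation
with binding-domain abundance.

Tracks are interval signals in 0-based half-open coordinates (bedGraph
convention). Binned values are coverage-weighted means over covered bases;
bins with no coverage are *missing* (NaN), not zero — no-data is distinct
from no-signal. Correlations against binding-domain abundance drop missing
bins pairwise and report raw Pearson r, mirroring the correlation heatmaps
used to annotate inferred binding domains with chromatin features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .profiles import BindingProfile

__all__ = [
    "Track",
    "CorrelationResult",
    "bin_track",
    "correlate_profile_tracks",
    "read_bedgraph",
]

MIN_SHARED_BINS = 4


@dataclass(frozen=True)
class Track:
    """Interval signal: DataFrame with columns chrom, start, end, value."""

    intervals: pd.DataFrame
    name: str = "track"

    def __post_init__(self) -> None:
        df = self.intervals
        required = ["chrom", "start", "end", "value"]
        if list(df.columns[:4]) != required:
            raise ValueError(f"track intervals need columns {required}")
        if len(df) and not (df["end"] > df["start"]).all():
            raise ValueError("track intervals must satisfy end > start")
        object.__setattr__(self, "intervals", df.sort_values(["chrom", "start"]).reset_index(drop=True))

    @classmethod
    def from_arrays(cls, chrom, starts, ends, values, name="track") -> "Track":
        return cls(
            pd.DataFrame({"chrom": chrom, "start": starts, "end": ends, "value": values}),
            name=name,
        )

    def write_bedgraph(self, path, header_lines: list[str] | None = None) -> None:
        with open(path, "w") as fh:
            for line in header_lines or []:
                fh.write(f"# {line}\n")
            self.intervals.to_csv(fh, sep="\t", header=False, index=False)


def read_bedgraph(path, name: str | None = None) -> Track:
    """Read a bedGraph (or 4-column BED-with-score) file."""
    df = pd.read_csv(
        path,
        sep=r"\s+",
        comment="#",
        header=None,
        names=["chrom", "start", "end", "value"],
        usecols=[0, 1, 2, 3],
        skiprows=lambda i: False,
    )
    # tolerate a UCSC "track ..." header line
    df = df[df["chrom"].astype(str) != "track"].reset_index(drop=True)
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    df["value"] = df["value"].astype(float)
    import os

    return Track(df, name=name or os.path.splitext(os.path.basename(str(path)))[0])


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson r between each binding-domain type and each track.

    ``matrix`` is (n_types, n_tracks); NaN marks cells with zero variance or
    fewer than MIN_SHARED_BINS usable bins. ``n_bins`` counts the bins that
    entered each cell.
    """

    matrix: np.ndarray
    n_bins: np.ndarray
    track_names: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.matrix,
            index=[f"type_{t}" for t in range(self.matrix.shape[0])],
            columns=self.track_names,
        )


def bin_track(
    track: Track,
    chrom: str,
    genomic_start: int,
    bin_size_bp: int,
    n_beads: int,
) -> np.ndarray:
    """Coverage-weighted mean signal per model bin; NaN where uncovered.

    Each interval contributes its value weighted by the number of bases it
    overlaps with the bin; the bin value is the weighted mean over covered
    bases only.
    """
    df = track.intervals
    if len(df):
        chroms = df["chrom"].unique()
        if not all(c == chrom for c in chroms):
            raise ValueError(f"track covers {list(chroms)}, expected only {chrom!r}")
    weighted = np.zeros(n_beads)
    covered = np.zeros(n_beads)
    region_end = genomic_start + n_beads * bin_size_bp
    for start, end, value in zip(df["start"], df["end"], df["value"]):
        s = max(int(start), genomic_start)
        e = min(int(end), region_end)
        if s >= e:
            continue
        b0 = (s - genomic_start) // bin_size_bp
        b1 = (e - 1 - genomic_start) // bin_size_bp
        for b in range(b0, b1 + 1):
            bin_lo = genomic_start + b * bin_size_bp
            bin_hi = bin_lo + bin_size_bp
            ov = min(e, bin_hi) - max(s, bin_lo)
            weighted[b] += ov * value
            covered[b] += ov
    with np.errstate(invalid="ignore"):
        out = weighted / covered
    out[covered == 0] = np.nan
    return out


def correlate_profile_tracks(profile: BindingProfile, tracks: list[Track]) -> CorrelationResult:
    """Pearson r between each type's abundance and each binned track.

    Bins missing in the track are dropped pairwise; cells with fewer than
    MIN_SHARED_BINS usable bins or zero variance on either side are NaN.
    """
    n_types = profile.n_types
    matrix = np.full((n_types, len(tracks)), np.nan)
    n_bins = np.zeros((n_types, len(tracks)), dtype=int)
    binned = [
        bin_track(tr, profile.chrom, profile.genomic_start, profile.bin_size_bp, profile.n_beads)
        for tr in tracks
    ]
    for k, vec in enumerate(binned):
        ok = ~np.isnan(vec)
        for t in range(n_types):
            x = profile.abundance[t][ok].astype(float)
            y = vec[ok]
            n_bins[t, k] = ok.sum()
            if ok.sum() < MIN_SHARED_BINS or np.std(x) == 0 or np.std(y) == 0:
                continue
            matrix[t, k] = np.corrcoef(x, y)[0, 1]
    return CorrelationResult(matrix, n_bins, [tr.name for tr in tracks])
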