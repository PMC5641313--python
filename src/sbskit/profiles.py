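"""Binding-site profiles: the per-bead annotation of binding-site types.

A locus is modelled as a chain of beads, one bead per genomic bin. Each bead
carries an integer copy number of every binding-site type ("color"); binders
of a cognate type bridge beads that carry that type. The :class:`BindingProfile`
is the central object shared by the synthetic generators, the polymer
simulator, and the inference machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "BindingProfile",
    "make_block_profile",
    "make_random_profile",
    "read_profile_tsv",
    "write_profile_tsv",
]


@dataclass(frozen=True)
class BindingProfile:
    """Per-bead binding-site type abundances over a genomic region.

    Parameters
    ----------
    abundance
        Integer array of shape ``(n_types, n_beads)``; entry ``(t, i)`` is the
        number of copies of binding-site type ``t`` on bead ``i``. Must be
        non-negative.
    bin_size_bp
        Genomic span of one bead, in base pairs.
    genomic_start
        0-based start coordinate of the first bead.
    chrom
        Chromosome label (purely a passthrough annotation).
    """

    abundance: np.ndarray
    bin_size_bp: int = 50_000
    genomic_start: int = 0
    chrom: str = "chrS"

    def __post_init__(self) -> None:
        a = np.asarray(self.abundance)
        if a.ndim != 2:
            raise ValueError(f"abundance must be 2-D (n_types, n_beads), got shape {a.shape}")
        if a.size and a.min() < 0:
            raise ValueError("abundance entries must be non-negative")
        if self.bin_size_bp <= 0:
            raise ValueError("bin_size_bp must be positive")
        if self.genomic_start < 0:
            raise ValueError("genomic_start must be non-negative")
        object.__setattr__(self, "abundance", np.ascontiguousarray(a, dtype=np.int64))

    @property
    def n_types(self) -> int:
        return self.abundance.shape[0]

    @property
    def n_beads(self) -> int:
        return self.abundance.shape[1]

    @property
    def region_length_bp(self) -> int:
        """Total modelled region length: ``n_beads * bin_size_bp``."""
        return self.n_beads * self.bin_size_bp

    def bin_starts(self) -> np.ndarray:
        """0-based start coordinate of every bin."""
        return self.genomic_start + self.bin_size_bp * np.arange(self.n_beads)

    def bead_type(self) -> np.ndarray:
        """Dominant type per bead (argmax of abundance), -1 where all zero."""
        t = np.argmax(self.abundance, axis=0)
        t[self.abundance.sum(axis=0) == 0] = -1
        return t

    def with_abundance(self, abundance: np.ndarray) -> "BindingProfile":
        return replace(self, abundance=abundance)


def make_block_profile(
    n_beads: int,
    blocks: list[tuple[int, int, int]],
    *,
    bin_size_bp: int = 50_000,
    genomic_start: int = 0,
    chrom: str = "chrS",
) -> BindingProfile:
    """Build a deterministic block profile from ``(start, end, type)`` intervals.

    Blocks are half-open bead intervals ``[start, end)``; a bead inside a block
    of type ``t`` gets one copy of that type. The classic two-color toy layout
    (alternating green/red blocks along the chain) is expressed this way.

    Raises
    ------
    ValueError
        If a block is out of range, or two blocks of *different* type overlap.
    """
    if n_beads < 1:
        raise ValueError("n_beads must be >= 1")
    n_types = max((t for _, _, t in blocks), default=-1) + 1
    abundance = np.zeros((n_types, n_beads), dtype=np.int64)
    claimed = np.full(n_beads, -1, dtype=np.int64)
    for start, end, t in blocks:
        if not (0 <= start < end <= n_beads):
            raise ValueError(f"block ({start}, {end}) out of range for n_beads={n_beads}")
        if t < 0:
            raise ValueError("type indices must be >= 0")
        clash = (claimed[start:end] >= 0) & (claimed[start:end] != t)
        if clash.any():
            i = start + int(np.argmax(clash))
            raise ValueError(
                f"conflicting block types at bead interval ({start}, {end}): "
                f"bead {i} already assigned type {claimed[i]}, cannot also be type {t}"
            )
        claimed[start:end] = t
        abundance[t, start:end] = 1
    return BindingProfile(abundance, bin_size_bp=bin_size_bp, genomic_start=genomic_start, chrom=chrom)


def make_alternating_blocks(n_beads: int, block_len: int, n_types: int = 2, **kw) -> BindingProfile:
    """Alternating equal-length blocks cycling through ``n_types`` types."""
    blocks = []
    t = 0
    for start in range(0, n_beads, block_len):
        blocks.append((start, min(start + block_len, n_beads), t))
        t = (t + 1) % n_types
    return make_block_profile(n_beads, blocks, **kw)


def make_random_profile(
    n_beads: int,
    n_types: int,
    mean_domain_len: float = 8.0,
    seed: int = 0,
    *,
    bin_size_bp: int = 50_000,
    genomic_start: int = 0,
    chrom: str = "chrS",
) -> BindingProfile:
    """Draw a random domain architecture: geometric-length runs of uniform type.

    Domain lengths are geometric with the given mean (the simplest
    one-parameter run-length model); each run is assigned a type uniformly at
    random. Resamples until every type appears at least once, so downstream
    type-recovery scoring is well defined. Deterministic in ``seed``.
    """
    if n_types < 1:
        raise ValueError("n_types must be >= 1")
    if n_types > n_beads:
        raise ValueError(f"n_types={n_types} exceeds n_beads={n_beads}")
    if mean_domain_len < 1:
        raise ValueError("mean_domain_len must be >= 1")
    rng = np.random.default_rng(seed)
    p = 1.0 / mean_domain_len
    for _ in range(1000):
        types = np.empty(n_beads, dtype=np.int64)
        i = 0
        while i < n_beads:
            run = int(rng.geometric(p))
            types[i : i + run] = rng.integers(n_types)
            i += run
        if len(np.unique(types)) == n_types:
            break
    else:  # pragma: no cover - vanishingly unlikely for sane parameters
        raise RuntimeError("failed to draw a profile containing every type")
    abundance = np.zeros((n_types, n_beads), dtype=np.int64)
    abundance[types, np.arange(n_beads)] = 1
    return BindingProfile(abundance, bin_size_bp=bin_size_bp, genomic_start=genomic_start, chrom=chrom)


def write_profile_tsv(profile: BindingProfile, path, header_lines: list[str] | None = None) -> None:
    """Serialize a profile as TSV: chrom, bin_start, bin_end, type_0..type_{n-1}."""
    starts = profile.bin_starts()
    df = pd.DataFrame({"chrom": profile.chrom, "bin_start": starts, "bin_end": starts + profile.bin_size_bp})
    for t in range(profile.n_types):
        df[f"type_{t}"] = profile.abundance[t]
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_profile_tsv(path) -> BindingProfile:
    df = pd.read_csv(path, sep="\t", comment="#")
    type_cols = [c for c in df.columns if c.startswith("type_")]
    if not type_cols:
        raise ValueError(f"no type_* columns found in {path}")
    type_cols.sort(key=lambda c: int(c.split("_")[1]))
    starts = df["bin_start"].to_numpy()
    bin_size = int(df["bin_end"].iloc[0] - df["bin_start"].iloc[0])
    return BindingProfile(
        df[type_cols].to_numpy().T,
        bin_size_bp=bin_size,
        genomic_start=int(starts[0]),
        chrom=str(df["chrom"].iloc[0]),
    )
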