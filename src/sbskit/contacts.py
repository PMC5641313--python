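"""Contact maps and contact-decay curves.

A :class:`ContactMap` is a symmetric bin-by-bin matrix of contact frequencies
(probabilities for simulated ensembles, arbitrary counts for Hi-C-like input).
A :class:`ContactCurve` is the average contact probability P(s) as a function
of genomic separation s in bins.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "ContactMap",
    "ContactCurve",
    "contact_curve",
    "map_pearson",
    "read_contact_matrix",
    "write_contact_matrix",
]


@dataclass(frozen=True)
class ContactMap:
    """Symmetric non-negative contact matrix with bin metadata."""

    matrix: np.ndarray
    chrom: str = "chrS"
    genomic_start: int = 0
    bin_size_bp: int = 50_000
    normalized: bool = False  # True when entries are contact probabilities in [0, 1]

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError(f"contact matrix must be square, got shape {m.shape}")
        if m.size and np.nanmin(m) < 0:
            raise ValueError("contact matrix entries must be non-negative")
        if not np.allclose(m, m.T, rtol=1e-8, atol=1e-12):
            raise ValueError("contact matrix must be symmetric (use read_contact_matrix to symmetrize input)")
        object.__setattr__(self, "matrix", np.ascontiguousarray(m))

    @property
    def n_beads(self) -> int:
        return self.matrix.shape[0]

    def offdiag_mean(self) -> float:
        n = self.n_beads
        if n < 2:
            raise ValueError("need at least 2 bins for an off-diagonal mean")
        m = self.matrix
        return float((m.sum() - np.trace(m)) / (n * (n - 1)))

    def upper_triangle(self, k: int = 1) -> np.ndarray:
        """Flattened strict upper triangle (off-diagonal entries counted once)."""
        iu = np.triu_indices(self.n_beads, k=k)
        return self.matrix[iu]


@dataclass(frozen=True)
class ContactCurve:
    """Average contact probability P(s) per genomic separation s (in bins)."""

    separations: np.ndarray
    probabilities: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        s = np.asarray(self.separations, dtype=float)
        p = np.asarray(self.probabilities, dtype=float)
        if s.shape != p.shape or s.ndim != 1:
            raise ValueError("separations and probabilities must be 1-D arrays of equal length")
        if s.size and (s.min() <= 0 or np.any(np.diff(s) <= 0)):
            raise ValueError("separations must be positive and strictly increasing")
        object.__setattr__(self, "separations", s)
        object.__setattr__(self, "probabilities", p)

    def rescaled(self, n_beads: int) -> "ContactCurve":
        """Express separations as fractions of chain length (s / N)."""
        return replace(self, separations=self.separations / n_beads)

    def interp_log(self, s_query: np.ndarray) -> np.ndarray:
        """Log-log linear interpolation of P at the queried separations."""
        logp = np.log(np.maximum(self.probabilities, 1e-300))
        return np.exp(np.interp(np.log(s_query), np.log(self.separations), logp))


def contact_curve(cmap: ContactMap) -> ContactCurve:
    """P(s): mean of matrix entries at each separation s = 1 .. n-1."""
    m = cmap.matrix
    n = m.shape[0]
    seps = np.arange(1, n)
    probs = np.array([np.mean(np.diagonal(m, offset=int(s))) for s in seps])
    return ContactCurve(seps.astype(float), probs)


def map_pearson(map_a: ContactMap, map_b: ContactMap) -> float:
    """Pearson correlation over strict upper-triangle entries of two maps."""
    if map_a.n_beads != map_b.n_beads:
        raise ValueError(f"dimension mismatch: {map_a.n_beads} vs {map_b.n_beads}")
    x = map_a.upper_triangle()
    y = map_b.upper_triangle()
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("map_pearson undefined: zero variance in upper-triangle entries")
    return float(np.corrcoef(x, y)[0, 1])


def read_contact_matrix(
    path,
    fmt: str = "auto",
    *,
    chrom: str = "chrS",
    genomic_start: int = 0,
    bin_size_bp: int = 50_000,
    n_bins: int | None = None,
) -> ContactMap:
    """Read a contact matrix from dense TSV or sparse triplet text.

    Dense input is symmetrized by averaging with its transpose. Triplet input
    (``i  j  value`` per line, 0-based bins) fills both (i, j) and (j, i);
    listing only one triangle is enough. NaNs and negative entries are
    rejected with a diagnostic.
    """
    raw = np.loadtxt(path, ndmin=2, comments="#")
    if fmt == "auto":
        fmt = "triplet" if raw.shape[1] == 3 and raw.shape[0] != 3 else "dense"
    if fmt == "dense":
        if raw.shape[0] != raw.shape[1]:
            raise ValueError(f"non-square dense matrix in {path}: shape {raw.shape}")
        bad = np.isnan(raw)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(f"{bad.sum()} NaN entries in {path}; first at ({i}, {j})")
        if raw.min() < 0:
            raise ValueError(f"negative entries in {path}")
        m = 0.5 * (raw + raw.T)
    elif fmt == "triplet":
        ii = raw[:, 0].astype(int)
        jj = raw[:, 1].astype(int)
        vv = raw[:, 2]
        if np.isnan(vv).any():
            raise ValueError(f"{np.isnan(vv).sum()} NaN values in triplet file {path}")
        if vv.min() < 0:
            raise ValueError(f"negative values in triplet file {path}")
        n = n_bins if n_bins is not None else int(max(ii.max(), jj.max())) + 1
        m = np.zeros((n, n))
        m[ii, jj] = vv
        m[jj, ii] = vv
    else:
        raise ValueError(f"unknown contact matrix format {fmt!r}")
    return ContactMap(m, chrom=chrom, genomic_start=genomic_start, bin_size_bp=bin_size_bp)


def write_contact_matrix(cmap: ContactMap, path, fmt: str = "dense", header_lines: list[str] | None = None) -> None:
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        if fmt == "dense":
            np.savetxt(fh, cmap.matrix, delimiter="\t", fmt="%.8g")
        elif fmt == "triplet":
            iu = np.triu_indices(cmap.n_beads)
            for i, j in zip(*iu):
                v = cmap.matrix[i, j]
                if v != 0:
                    fh.write(f"{i}\t{j}\t{v:.8g}\n")
        else:
            raise ValueError(f"unknown contact matrix format {fmt!r}")
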