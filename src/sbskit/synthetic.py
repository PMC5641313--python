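"""Synthetic loci with planted architectures.

Generators for the fixtures every downstream stage is validated on: planted
block or random binding-domain profiles (see :mod:`sbskit.profiles`),
contact maps built from the mean-field forward model with multiplicative
log-normal noise, and epigenomic-like tracks enriched where a chosen binding
type is abundant. All generators are pure functions of their arguments
including the seed.

Noise choices: contacts get multiplicative log-normal noise (Hi-C counts are
overdispersed and ratio noise is scale-free); tracks get additive Gaussian
noise floored at zero.
"""

from __future__ import annotations

import numpy as np

from .contacts import ContactMap
from .inference import ForwardParams, forward_contact_model
from .profiles import BindingProfile
from .tracks import Track

__all__ = ["synth_contact_map", "synth_track"]


def synth_contact_map(
    profile: BindingProfile,
    decay_exponent: float = 1.0,
    enrichment: float = 1.0,
    noise_cv: float = 0.05,
    seed: int = 0,
    saturation: float = 1.0,
) -> ContactMap:
    """Forward-model contact map with multiplicative log-normal noise.

    The noise field has unit mean and coefficient of variation ``noise_cv``;
    it is drawn on the upper triangle and mirrored, so the output is exactly
    symmetric. ``noise_cv=0`` reproduces the forward model bit-for-bit.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    base = forward_contact_model(profile, ForwardParams(decay_exponent, enrichment, saturation))
    if noise_cv == 0:
        return base
    rng = np.random.default_rng(seed)
    n = profile.n_beads
    sigma2 = np.log1p(noise_cv**2)
    iu = np.triu_indices(n, k=1)
    mult = np.ones((n, n))
    draws = rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=len(iu[0]))
    mult[iu] = draws
    mult.T[iu] = draws
    return ContactMap(
        base.matrix * mult,
        chrom=base.chrom,
        genomic_start=base.genomic_start,
        bin_size_bp=base.bin_size_bp,
        normalized=False,
    )


def synth_track(
    profile: BindingProfile,
    type_index: int,
    noise_sd: float = 0.0,
    seed: int = 0,
    name: str | None = None,
) -> Track:
    """A per-bin signal track planted on one binding-site type.

    The signal is the abundance row of ``type_index`` plus Gaussian noise,
    floored at zero — a caricature of a ChIP-seq-like feature enriched where
    the corresponding binding domain lives.
    """
    if not (0 <= type_index < profile.n_types):
        raise ValueError(f"type_index {type_index} out of range [0, {profile.n_types})")
    rng = np.random.default_rng(seed)
    values = profile.abundance[type_index].astype(float)
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=values.shape)
    values = np.maximum(values, 0.0)
    starts = profile.bin_starts()
    return Track.from_arrays(
        profile.chrom,
        starts,
        starts + profile.bin_size_bp,
        values,
        name=name or f"planted_type_{type_index}",
    )
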