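"""Gaussian interaction profile (GIP) kernel similarities and their fusion
with the upstream semantic / functional similarity matrices.

The GIP kernel scores two nodes by a Gaussian kernel on the distance between
their binary interaction profiles,

    K(x_i, x_j) = exp(-r ||IP(x_i) - IP(x_j)||^2),

with the effective bandwidth r obtained from a raw bandwidth parameter r'
normalised by the mean squared profile norm over the node set.  The
integrated similarity keeps the upstream semantic/functional value wherever
it is nonzero and falls back to the kernel elsewhere, repairing the isolated
(all-zero) rows that the upstream matrices typically contain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import AssociationMatrix, SimilarityMatrix
from .exceptions import DegenerateBandwidthError, ValidationError

__all__ = [
    "GipBandwidth",
    "effective_bandwidth",
    "gip_disease_similarity",
    "gip_mirna_similarity",
    "integrate_disease_similarity",
    "integrate_mirna_similarity",
]


@dataclass(frozen=True)
class GipBandwidth:
    """Raw (r') and effective (r) kernel bandwidth.

    effective = raw / mean_i ||IP(x_i)||^2 over the node set.
    """

    raw: float
    effective: float


def effective_bandwidth(profiles: np.ndarray, raw: float) -> GipBandwidth:
    """Normalise a raw bandwidth by the mean squared norm of the profiles.

    ``profiles`` holds one interaction profile per row.  Raises
    :class:`DegenerateBandwidthError` when every profile is zero, since the
    normaliser is then a division by zero; a silent fallback would mask
    upstream data errors.
    """
    if raw <= 0:
        raise ValidationError(f"raw bandwidth must be positive, got {raw}")
    mean_sq_norm = float(np.square(profiles, dtype=float).sum(axis=1).mean())
    if mean_sq_norm == 0.0:
        raise DegenerateBandwidthError(
            "all interaction profiles are zero; the kernel bandwidth is undefined"
        )
    return GipBandwidth(raw=float(raw), effective=float(raw) / mean_sq_norm)


def _gip_kernel(profiles: np.ndarray, ids: list[str], raw_bandwidth: float) -> SimilarityMatrix:
    bw = effective_bandwidth(profiles, raw_bandwidth)
    p = profiles.astype(float)
    sq_norms = np.square(p).sum(axis=1)
    # ||u - v||^2 = ||u||^2 + ||v||^2 - 2 u.v ; profiles are binary so this is exact
    # up to float rounding, which the clip removes.
    sq_dist = sq_norms[:, None] + sq_norms[None, :] - 2.0 * (p @ p.T)
    np.clip(sq_dist, 0.0, None, out=sq_dist)
    kernel = np.exp(-bw.effective * sq_dist)
    kernel = (kernel + kernel.T) / 2.0
    np.fill_diagonal(kernel, 1.0)
    return SimilarityMatrix(kernel, list(ids), kind="gip")


def gip_disease_similarity(
    assoc: AssociationMatrix, raw_bandwidth: float = 1.0
) -> SimilarityMatrix:
    """GIP kernel over diseases: profiles are the columns of A."""
    return _gip_kernel(assoc.values.T, assoc.disease_ids, raw_bandwidth)


def gip_mirna_similarity(
    assoc: AssociationMatrix, raw_bandwidth: float = 1.0
) -> SimilarityMatrix:
    """GIP kernel over miRNAs: profiles are the rows of A."""
    return _gip_kernel(assoc.values, assoc.mirna_ids, raw_bandwidth)


def _integrate(upstream: SimilarityMatrix, kernel: SimilarityMatrix) -> SimilarityMatrix:
    if upstream.ids != kernel.ids:
        missing = sorted(set(upstream.ids) ^ set(kernel.ids))
        raise ValidationError(
            "similarity matrices are over different node sets or orders; "
            f"symmetric difference of ids: {missing[:10]}"
        )
    # The zero test is exact: a zero entry encodes "no upstream information",
    # not a small similarity, so no tolerance is applied.
    fused = np.where(upstream.values != 0.0, upstream.values, kernel.values)
    return SimilarityMatrix(fused, list(upstream.ids), kind="integrated")


def integrate_disease_similarity(
    dss: SimilarityMatrix, dgs: SimilarityMatrix
) -> SimilarityMatrix:
    """Integrated disease similarity D_S: semantic value where nonzero, else kernel."""
    return _integrate(dss, dgs)


def integrate_mirna_similarity(
    mfs: SimilarityMatrix, mgs: SimilarityMatrix
) -> SimilarityMatrix:
    """Integrated miRNA similarity M_S: functional value where nonzero, else kernel."""
    return _integrate(mfs, mgs)
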