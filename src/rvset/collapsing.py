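"""Ultra-rare-variant collapsing.

Variants with minor allele count (MAC) at or below a threshold (default 10)
are merged into a single pseudo-marker before set-based testing; the collapsed
marker is then tested together with the remaining MAC > threshold variants.
Collapsing de-sparsifies the testing set — singletons and doubletons no longer
enter the score statistic as near-degenerate columns — which is what restores
type I error control for variance-component tests under heavy case-control
imbalance.

Three weighting schemes are supported:

``beta_default``
    Collapse raw dosages by per-sample maximum, then weight every column
    (collapsed one included) by the Beta(1, 25) density at its MAF.
``user_weights``
    Multiply each ultra-rare column by its user weight first, then collapse by
    per-sample maximum of the *weighted* dosages; weights are thereby folded
    into the marker matrix and the reported weight vector is all ones.
``none``
    The user-weight scheme with unit weights everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy import stats

from .variant_io import GeneVariantSet

DEFAULT_MAC_THRESHOLD = 10.0


class WeightKind(str, Enum):
    BETA_DEFAULT = "beta_default"
    USER_WEIGHTS = "user_weights"
    NONE = "none"


@dataclass(frozen=True)
class WeightScheme:
    """Per-marker weighting scheme used during collapsing and testing."""

    kind: WeightKind = WeightKind.BETA_DEFAULT
    beta_a: float = 1.0
    beta_b: float = 25.0
    user_w: np.ndarray | None = None

    def __post_init__(self) -> None:
        kind = WeightKind(self.kind)
        object.__setattr__(self, "kind", kind)
        if kind is WeightKind.USER_WEIGHTS:
            if self.user_w is None:
                raise ValueError("user_weights scheme requires user_w")
            w = np.asarray(self.user_w, dtype=float)
            if np.any(w < 0):
                raise ValueError("user weights must be non-negative")
            object.__setattr__(self, "user_w", w)
        elif self.user_w is not None:
            raise ValueError(f"user_w only valid with kind=user_weights, not {kind.value}")


@dataclass
class CollapsedSet:
    """Post-collapsing marker matrix, weights and provenance.

    ``marker_matrix`` is N x K where K = #(MAC > threshold) columns plus one
    collapsed column if any ultra-rare variant existed.  ``provenance`` lists
    the variant ids merged into the collapsed column (empty if none).
    """

    gene_id: str
    marker_matrix: np.ndarray
    weights: np.ndarray
    marker_maf: np.ndarray
    variant_ids: list[str]
    provenance: list[str] = field(default_factory=list)
    collapsed_index: int | None = None
    mac_threshold: float = DEFAULT_MAC_THRESHOLD
    scheme_kind: WeightKind = WeightKind.BETA_DEFAULT

    @property
    def n_markers(self) -> int:
        return self.marker_matrix.shape[1]

    @property
    def collapsed(self) -> bool:
        return self.collapsed_index is not None


def beta_weight(maf, a: float = 1.0, b: float = 25.0):
    """Beta(a, b) density evaluated at the MAF — the standard rare-variant
    up-weighting; with the defaults this is ``25 * (1 - f)**24``, strictly
    decreasing in f and equal to 25 at f = 0."""
    maf = np.asarray(maf, dtype=float)
    if np.any(maf < 0) or np.any(maf > 0.5):
        raise ValueError("maf must lie in [0, 0.5]")
    out = stats.beta.pdf(maf, a, b)
    return float(out) if out.ndim == 0 else out


def collapse(
    gvs: GeneVariantSet,
    scheme: WeightScheme = WeightScheme(),
    mac_threshold: float = DEFAULT_MAC_THRESHOLD,
) -> CollapsedSet:
    """Merge MAC <= threshold variants of a testing set into one marker.

    The collapsed dosage of a sample is the maximum raw (``beta_default``) or
    weighted (``user_weights`` / ``none``) dosage among the ultra-rare
    variants the sample carries; samples carrying none get 0.  Column order of
    surviving MAC > threshold variants is preserved; the collapsed column, if
    present, is appended last.
    """
    if mac_threshold < 0:
        raise ValueError("mac_threshold must be >= 0")
    if np.all(gvs.mac <= 0):
        raise ValueError(f"gene {gvs.gene_id}: all columns monomorphic")
    scheme = scheme if isinstance(scheme, WeightScheme) else WeightScheme(scheme)

    ultra = gvs.mac <= mac_threshold
    keep = ~ultra
    n = gvs.n_samples

    if scheme.kind is WeightKind.USER_WEIGHTS:
        user_w = np.asarray(scheme.user_w, dtype=float)
        if user_w.shape != (gvs.n_variants,):
            raise ValueError("user_w must have one weight per input variant")
    else:
        user_w = np.ones(gvs.n_variants)

    cols = [gvs.dosage[:, j] if scheme.kind is WeightKind.BETA_DEFAULT
            else gvs.dosage[:, j] * user_w[j]
            for j in np.flatnonzero(keep)]
    mafs = list(gvs.maf[keep])
    ids = [gvs.variants[j].variant_id for j in np.flatnonzero(keep)]
    provenance: list[str] = []
    collapsed_index = None

    if ultra.any():
        uidx = np.flatnonzero(ultra)
        if scheme.kind is WeightKind.BETA_DEFAULT:
            merged = gvs.dosage[:, uidx].max(axis=1)
        else:
            merged = (gvs.dosage[:, uidx] * user_w[uidx]).max(axis=1)
        collapsed_index = len(cols)
        cols.append(merged)
        # allele-frequency analogue of the merged column, capped at 0.5
        mafs.append(min(float(merged.sum()) / (2.0 * n), 0.5))
        ids.append(f"{gvs.gene_id}:collapsed")
        provenance = [gvs.variants[int(j)].variant_id for j in uidx]

    matrix = np.column_stack(cols)
    marker_maf = np.asarray(mafs)
    if scheme.kind is WeightKind.BETA_DEFAULT:
        weights = beta_weight(marker_maf, scheme.beta_a, scheme.beta_b)
    else:
        # weights already folded into the dosages; downstream must not re-weight
        weights = np.ones(matrix.shape[1])
    return CollapsedSet(
        gene_id=gvs.gene_id,
        marker_matrix=matrix,
        weights=np.atleast_1d(weights),
        marker_maf=marker_maf,
        variant_ids=ids,
        provenance=provenance,
        collapsed_index=collapsed_index,
        mac_threshold=float(mac_threshold),
        scheme_kind=scheme.kind,
    )
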