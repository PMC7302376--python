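"""Split barcode-specific fragments into molecule-specific fragments.

A 10X-style droplet tags on average ~10 long DNA molecules with the same
barcode, so a merged barcode fragment mixes alleles from several (possibly
different-haplotype) molecules.  Because molecule coverage of the genome is
very low, molecules sharing a barcode are usually far apart; clustering the
genomic positions of a barcode fragment's calls therefore recovers the
individual molecules.  Clustering is 1-D mean shift with a flat (uniform)
kernel whose bandwidth defaults to half the expected molecule length.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .fragio import Fragment, VariantSite


@dataclass(frozen=True, slots=True)
class MeanShiftConfig:
    """Parameters of the molecule-splitting mean shift.

    ``bandwidth`` is in bp (use half the expected molecule length);
    ``convergence_tol`` stops the mode iteration once the shift falls below
    it; clusters with fewer than ``min_calls_per_molecule`` calls are
    discarded (a single covered SNP cannot inform phasing).
    """

    bandwidth: float
    convergence_tol: float = 1.0
    max_iter: int = 300
    min_calls_per_molecule: int = 2

    def __post_init__(self) -> None:
        if self.bandwidth <= 0:
            raise ValueError("bandwidth must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


def mean_shift_1d(
    positions: Sequence[float],
    bandwidth: float,
    convergence_tol: float = 1.0,
    max_iter: int = 300,
) -> np.ndarray:
    """Flat-kernel mean shift on 1-D points; returns a label per point.

    Every point seeds a mode search (iterated mean of in-bandwidth points);
    converged modes closer than the bandwidth are merged, preferring modes
    supported by more points; points are assigned to the nearest surviving
    mode.  Deterministic.  Labels are 0-based in ascending mode order.
    """
    pts = np.asarray(positions, dtype=float)
    n = pts.size
    if n == 0:
        return np.empty(0, dtype=int)
    modes = np.unique(pts).astype(float)
    for _ in range(max_iter):
        within = np.abs(modes[:, None] - pts[None, :]) <= bandwidth
        counts = within.sum(axis=1)
        new = (within * pts[None, :]).sum(axis=1) / np.maximum(counts, 1)
        shift = np.abs(new - modes).max()
        modes = new
        if shift < convergence_tol:
            break
    # Merge modes within one bandwidth of each other: visit modes by
    # decreasing support, suppressing unvisited modes in their window.
    within = np.abs(modes[:, None] - pts[None, :]) <= bandwidth
    support = within.sum(axis=1)
    order = np.lexsort((modes, -support))
    keep: list[float] = []
    suppressed = np.zeros(modes.size, dtype=bool)
    for i in order:
        if suppressed[i]:
            continue
        keep.append(modes[i])
        suppressed |= np.abs(modes - modes[i]) <= bandwidth
    centers = np.sort(np.asarray(keep))
    return np.argmin(np.abs(pts[:, None] - centers[None, :]), axis=1)


def split_barcode_fragment(
    fragment: Fragment,
    variants: Sequence[VariantSite],
    config: MeanShiftConfig,
) -> list[Fragment]:
    """Partition one barcode fragment's calls into molecule fragments.

    Clusters are ordered by ascending leftmost genomic position and named
    ``<barcode>_<ordinal>`` with ordinals starting at 1.  Clusters with
    fewer than ``min_calls_per_molecule`` calls are discarded, so the
    emitted calls are a subset of the input calls.
    """
    if fragment.origin != "barcode":
        raise ValueError("split_barcode_fragment expects a barcode fragment")
    pos_of = {v.index: v.position for v in variants}
    positions = [pos_of[c.variant_index] for c in fragment.calls]
    labels = mean_shift_1d(
        positions, config.bandwidth, config.convergence_tol, config.max_iter
    )
    clusters: dict[int, list] = {}
    for call, lab, pos in zip(fragment.calls, labels, positions):
        clusters.setdefault(int(lab), []).append((pos, call))
    ordered = sorted(
        (min(p for p, _ in members), members) for members in clusters.values()
    )
    out: list[Fragment] = []
    ordinal = 0
    for _, members in ordered:
        calls = tuple(c for _, c in sorted(members, key=lambda m: m[1].variant_index))
        if len(calls) < config.min_calls_per_molecule:
            continue
        ordinal += 1
        out.append(
            Fragment(
                id=f"{fragment.barcode}_{ordinal}",
                origin="molecule",
                calls=calls,
                barcode=fragment.barcode,
                molecule_ordinal=ordinal,
            )
        )
    return out


def split_all(
    fragments: Iterable[Fragment],
    variants: Sequence[VariantSite],
    config: MeanShiftConfig,
) -> list[Fragment]:
    """Apply molecule splitting to every barcode fragment.

    Fragments without a barcode (or not of barcode origin) pass through
    unchanged.  Output is sorted by first variant index.
    """
    out: list[Fragment] = []
    for frag in fragments:
        if frag.origin == "barcode" and frag.barcode is not None:
            out.extend(split_barcode_fragment(frag, variants, config))
        else:
            out.append(frag)
    out.sort(key=lambda f: (f.first_index, f.id))
    return out
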