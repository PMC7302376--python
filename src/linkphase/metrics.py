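"""Evaluation of reconstructed haplotypes against a planted ground truth.

Three criteria are computed per haplotype block and averaged:

* **reconstruction rate** (local accuracy): one minus the per-allele
  mismatch fraction, minimized over all K! pairings of reconstructed and
  true haplotypes;
* **vector error rate** (global accuracy): the minimum number of
  haplotype-assignment switches needed along the block for the
  reconstruction to match the truth, divided by the block length.  The
  minimum is taken lexicographically — residual allele mismatches first,
  switches second — by dynamic programming over permutations;
* **MEC** (reference-free compatibility): total mismatches between the
  fragments and their best-matching reconstructed haplotypes.

Block length statistics report the mean block size in SNPs and the N50
block span in bp, matching the two conventions used for linked-read
haplotype assemblies.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .core import GAP, HaplotypeBlock
from .fragio import Fragment


@dataclass
class GroundTruth:
    """K gap-free haplotypes over all M variant sites."""

    haplotypes: np.ndarray  # (K, M) allele codes
    positions: np.ndarray  # (M,) genomic bp, strictly increasing

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int64)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.haplotypes.ndim != 2:
            raise ValueError("haplotypes must be (K, M)")
        if self.haplotypes.shape[1] != self.positions.size:
            raise ValueError("positions length must match haplotype length")
        if np.any(self.haplotypes < 0):
            raise ValueError("ground truth may not contain gaps")

    @property
    def K(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def M(self) -> int:
        return self.haplotypes.shape[1]


def write_truth(truth: GroundTruth, path: str | Path) -> None:
    """Plain-text truth table: 1-based index, position, K allele columns."""
    with open(path, "w") as fh:
        for j in range(truth.M):
            cols = [str(j + 1), str(truth.positions[j])]
            cols += [str(a) for a in truth.haplotypes[:, j]]
            fh.write("\t".join(cols) + "\n")


def read_truth(path: str | Path) -> GroundTruth:
    rows = []
    positions = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            toks = line.split()
            positions.append(int(toks[1]))
            rows.append([int(t) for t in toks[2:]])
    haps = np.asarray(rows, dtype=np.int64).T
    return GroundTruth(haplotypes=haps, positions=np.asarray(positions))


def _align(block: HaplotypeBlock, truth: GroundTruth) -> tuple[np.ndarray, np.ndarray]:
    """Restrict truth to the block's variant indices (1-based)."""
    idx = np.asarray(block.variant_indices, dtype=np.int64) - 1
    if idx.min() < 0 or idx.max() >= truth.M:
        raise ValueError("block variant indices outside the truth")
    if block.K != truth.K:
        raise ValueError(f"ploidy mismatch: block {block.K} vs truth {truth.K}")
    return block.haplotypes, truth.haplotypes[:, idx]


def reconstruction_rate(
    block: HaplotypeBlock,
    truth: GroundTruth,
    gaps_as_errors: bool = False,
) -> float:
    """1 - (mismatches under the best haplotype pairing) / (evaluated alleles).

    By default positions where a reconstructed haplotype has a gap are
    excluded both from the mismatch count and from the denominator;
    ``gaps_as_errors`` counts them as mismatches over the full K*L
    denominator instead.  The pairing minimum is exhaustive over K!
    (ploidy <= 8).
    """
    pred, true = _align(block, truth)
    K, L = pred.shape
    if K > 8:
        raise ValueError("permutation search limited to K <= 8")
    covered = pred != GAP
    # pairwise mismatch counts: pred row k vs truth row k2
    mism = np.zeros((K, K), dtype=np.int64)
    for k in range(K):
        for k2 in range(K):
            if gaps_as_errors:
                mism[k, k2] = int(np.sum((pred[k] != true[k2]) | ~covered[k]))
            else:
                mism[k, k2] = int(np.sum(covered[k] & (pred[k] != true[k2])))
    denom = K * L if gaps_as_errors else int(covered.sum())
    if denom == 0:
        return 0.0
    best = min(
        sum(mism[k, p[k]] for k in range(K))
        for p in itertools.permutations(range(K))
    )
    return 1.0 - best / denom


def vector_error_rate(
    block: HaplotypeBlock, truth: GroundTruth
) -> tuple[int, float]:
    """Minimum switches to match the truth, and that count per site.

    Dynamic program over positions with one state per permutation of the K
    haplotypes.  Position cost = allele mismatches under the permutation
    (gap positions cost nothing); transition cost = number of indices at
    which consecutive permutations differ.  The objective is lexicographic
    (mismatches, then switches); the switch count of an optimal path is
    returned together with switches / L.
    """
    pred, true = _align(block, truth)
    K, L = pred.shape
    if K > 6:
        raise ValueError("vector-error DP limited to K <= 6")
    perms = list(itertools.permutations(range(K)))
    P = len(perms)
    # transition cost between permutations
    trans = np.zeros((P, P), dtype=np.int64)
    for a in range(P):
        for bb in range(P):
            trans[a, bb] = sum(1 for k in range(K) if perms[a][k] != perms[bb][k])
    covered = pred != GAP
    BIG = np.int64(K * L + 1)  # any mismatch outweighs all possible switches
    # cost of position j under permutation p: mismatches * BIG
    pos_cost = np.zeros((L, P), dtype=np.int64)
    for pi, p in enumerate(perms):
        sel = true[list(p), :]
        pos_cost[:, pi] = np.sum(covered & (pred != sel), axis=0) * BIG
    dp = pos_cost[0].copy()
    for j in range(1, L):
        dp = (dp[:, None] + trans).min(axis=0) + pos_cost[j]
    total = int(dp.min())
    switches = total % int(BIG)
    return switches, switches / L if L else 0.0


def mec(fragments: Sequence[Fragment], block: HaplotypeBlock) -> int:
    """Total mismatches between fragments and their closest haplotypes.

    Calls at variant indices outside the block and haplotype gap positions
    are ignored.  Only haplotypes sharing at least one covered (non-gap)
    site with a fragment are eligible as its nearest haplotype — without
    this, a sparsely covered haplotype absorbs fragments at zero cost.
    """
    col = {s: j for j, s in enumerate(block.variant_indices)}
    total = 0
    for frag in fragments:
        per_hap = np.zeros(block.K, dtype=np.int64)
        overlap = np.zeros(block.K, dtype=np.int64)
        for c in frag.calls:
            j = col.get(c.variant_index)
            if j is None:
                continue
            hap_alleles = block.haplotypes[:, j]
            covered = hap_alleles != GAP
            per_hap += covered & (hap_alleles != c.allele)
            overlap += covered
        if np.any(overlap > 0):
            total += int(per_hap[overlap > 0].min())
    return total


def block_stats(
    blocks: Sequence[HaplotypeBlock], positions: np.ndarray
) -> tuple[float, float]:
    """(mean block length in SNPs, N50 block span in bp).

    ``positions`` maps 1-based variant index -> genomic bp.  The N50 is
    the span of the block at which the cumulative span (blocks sorted by
    decreasing span) first reaches half the total span.
    """
    if not blocks:
        return 0.0, 0.0
    positions = np.asarray(positions)
    mean_len = float(np.mean([b.n_sites for b in blocks]))
    spans = []
    for b in blocks:
        first = positions[b.variant_indices[0] - 1]
        last = positions[b.variant_indices[-1] - 1]
        spans.append(float(last - first))
    spans.sort(reverse=True)
    half = sum(spans) / 2.0
    acc = 0.0
    n50 = spans[-1]
    for s in spans:
        acc += s
        if acc >= half:
            n50 = s
            break
    return mean_len, float(n50)


@dataclass
class EvaluationReport:
    """Aggregated evaluation over all blocks of a run."""

    reconstruction_rate: float
    reconstruction_rate_weighted: float
    vector_error_rate: float
    vector_error_rate_weighted: float
    total_switches: int
    total_mec: int
    mean_block_len_snps: float
    n50_bp: float
    n_blocks: int
    n_sites_evaluated: int
    n_gap_positions: int
    per_block: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "reconstruction_rate": self.reconstruction_rate,
            "reconstruction_rate_weighted": self.reconstruction_rate_weighted,
            "vector_error_rate": self.vector_error_rate,
            "vector_error_rate_weighted": self.vector_error_rate_weighted,
            "total_switches": self.total_switches,
            "total_mec": self.total_mec,
            "mean_block_len_snps": self.mean_block_len_snps,
            "n50_bp": self.n50_bp,
            "n_blocks": self.n_blocks,
            "n_sites_evaluated": self.n_sites_evaluated,
            "n_gap_positions": self.n_gap_positions,
            "per_block": self.per_block,
        }


def evaluate_blocks(
    blocks: Sequence[HaplotypeBlock],
    truth: GroundTruth,
    fragments_per_block: Sequence[Sequence[Fragment]] | None = None,
) -> EvaluationReport:
    """Per-block metrics with unweighted and length-weighted averages."""
    if not blocks:
        return EvaluationReport(0.0, 0.0, 0.0, 0.0, 0, 0, 0.0, 0.0, 0, 0, 0)
    rrs, vers, lens, per_block = [], [], [], []
    switches_total = 0
    mec_total = 0
    gaps = 0
    for i, b in enumerate(blocks):
        rr = reconstruction_rate(b, truth)
        sw, ver = vector_error_rate(b, truth)
        m = b.mec
        if fragments_per_block is not None:
            m = mec(fragments_per_block[i], b)
        rrs.append(rr)
        vers.append(ver)
        lens.append(b.n_sites)
        switches_total += sw
        mec_total += m
        gaps += int(np.sum(b.haplotypes == GAP))
        per_block.append(
            {"sites": b.n_sites, "rr": rr, "ver": ver, "switches": sw, "mec": m}
        )
    lens_arr = np.asarray(lens, dtype=float)
    wsum = lens_arr.sum()
    mean_len, n50 = block_stats(blocks, truth.positions)
    return EvaluationReport(
        reconstruction_rate=float(np.mean(rrs)),
        reconstruction_rate_weighted=float(np.dot(rrs, lens_arr) / wsum),
        vector_error_rate=float(np.mean(vers)),
        vector_error_rate_weighted=float(np.dot(vers, lens_arr) / wsum),
        total_switches=switches_total,
        total_mec=mec_total,
        mean_block_len_snps=mean_len,
        n50_bp=n50,
        n_blocks=len(blocks),
        n_sites_evaluated=int(wsum),
        n_gap_positions=gaps,
        per_block=per_block,
    )
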