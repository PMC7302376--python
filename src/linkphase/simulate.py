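"""Synthetic polyploid linked-read data at desk scale.

Generates planted K-ploid haplotypes over a region and 10X-style barcode
fragments derived from long molecules: molecules are placed uniformly,
assigned uniformly to haplotypes, grouped onto barcodes (several molecules
per barcode, as in a real droplet), and each SNP inside a molecule is
observed with a configurable probability and error rate.  The simulation
is fragment-level: the statistical object that matters downstream is the
per-SNP observation process, so reads are only materialized by the
optional SAM/VCF fixture emitter.

All outputs are deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .fragio import (
    AlleleCall,
    Fragment,
    VariantSite,
    merge_by_barcode,
)
from .metrics import GroundTruth

_NUCS = ("A", "C", "G", "T")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of one simulation.

    Defaults follow the linked-read regime the pipeline targets: SNP rate
    0.01/bp, 50 kb molecules, 10 molecules per barcode, molecule coverage
    0.2 per haploid; ``obs_prob`` models read coverage within a molecule
    (the probability that a SNP spanned by the molecule is actually
    observed) and ``error_rate`` is the per-observed-allele error
    (Illumina-scale 0.001 by default).
    """

    ploidy: int = 3
    genome_length: int = 1_000_000
    snp_rate: float = 0.01
    molecule_length: float = 50_000.0
    molecule_length_dist: str = "fixed"  # fixed | exponential
    molecules_per_barcode: int = 10
    barcode_dist: str = "fixed"  # fixed | poisson
    molecule_coverage: float = 0.2  # per haploid
    obs_prob: float = 0.9
    error_rate: float = 0.001
    quality: int = 30
    seed: int = 0
    gap_interval: tuple[int, int] | None = None  # N-region without SNPs

    def __post_init__(self) -> None:
        for name in ("snp_rate", "obs_prob", "error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.ploidy < 2:
            raise ValueError("ploidy must be >= 2")
        if self.genome_length <= self.molecule_length:
            raise ValueError("genome_length must exceed molecule_length")


@dataclass
class MoleculeRecord:
    """Ground-truth provenance of one simulated molecule."""

    barcode: str
    ordinal: int  # by leftmost position within the barcode, 1-based
    haplotype: int
    start: int
    end: int
    n_calls: int


@dataclass
class SimResult:
    variants: list[VariantSite]
    truth: GroundTruth
    barcode_fragments: list[Fragment]
    molecule_fragments: list[Fragment]
    molecule_table: list[MoleculeRecord]


def generate_truth(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[list[VariantSite], GroundTruth]:
    """Plant heterozygous biallelic SNPs and K haplotype rows.

    Positions are drawn uniformly at ``snp_rate`` over the region
    (excluding the gap interval); each site gets a dosage uniform on
    1..K-1 and its alternate allele lands on a uniformly chosen subset of
    the K rows, so every site is heterozygous.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    K, G = config.ploidy, config.genome_length
    eligible = np.arange(1, G + 1)
    if config.gap_interval is not None:
        lo, hi = config.gap_interval
        eligible = eligible[(eligible < lo) | (eligible > hi)]
    n_snps = rng.binomial(eligible.size, config.snp_rate)
    if n_snps == 0:
        raise ValueError(
            "no SNPs drawn; increase genome_length or snp_rate"
        )
    positions = np.sort(rng.choice(eligible, size=n_snps, replace=False))
    haps = np.zeros((K, n_snps), dtype=np.int64)
    variants: list[VariantSite] = []
    for j, pos in enumerate(positions):
        dosage = int(rng.integers(1, K))
        rows = rng.choice(K, size=dosage, replace=False)
        haps[rows, j] = 1
        ref = _NUCS[rng.integers(0, 4)]
        alt = _NUCS[(rng.integers(1, 4) + _NUCS.index(ref)) % 4]
        variants.append(
            VariantSite(
                index=j + 1,
                position=int(pos),
                ref_allele=ref,
                alt_alleles=(alt,),
                dosage=dosage,
                chrom="sim",
            )
        )
    return variants, GroundTruth(haplotypes=haps, positions=positions)


def simulate_fragments(
    variants: Sequence[VariantSite],
    truth: GroundTruth,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> SimResult:
    """Simulate molecules, their allele observations, and barcode merging.

    The number of molecules is round(coverage * G * K / molecule_length);
    each is assigned uniformly to a haplotype, observes every spanned SNP
    with probability ``obs_prob``, flips an observed allele with
    probability ``error_rate``, and is grouped with ``molecules_per_barcode``
    mates onto one barcode.  Molecule calls sharing a barcode are merged
    through the same conflict rules as real barcode merging.  Molecule and
    barcode fragments with fewer than two calls are dropped.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    K, G = config.ploidy, config.genome_length
    positions = truth.positions
    n_mol = int(round(config.molecule_coverage * G * K / config.molecule_length))
    if n_mol < 1:
        raise ValueError("configuration yields zero molecules")
    starts = rng.integers(1, G + 1, size=n_mol)
    if config.molecule_length_dist == "exponential":
        lengths = np.maximum(
            rng.exponential(config.molecule_length, size=n_mol), 1.0
        )
    else:
        lengths = np.full(n_mol, float(config.molecule_length))
    ends = np.minimum(starts + lengths.astype(np.int64) - 1, G)
    hap_of = rng.integers(0, K, size=n_mol)

    # group molecules onto barcodes
    order = rng.permutation(n_mol)
    barcode_of = np.empty(n_mol, dtype=np.int64)
    if config.barcode_dist == "poisson":
        bc = 0
        i = 0
        while i < n_mol:
            size = max(int(rng.poisson(config.molecules_per_barcode)), 1)
            barcode_of[order[i : i + size]] = bc
            i += size
            bc += 1
    else:
        m = config.molecules_per_barcode
        for i, mol in enumerate(order):
            barcode_of[mol] = i // m

    mol_calls: list[list[AlleleCall]] = []
    for mol in range(n_mol):
        lo = np.searchsorted(positions, starts[mol], side="left")
        hi = np.searchsorted(positions, ends[mol], side="right")
        calls: list[AlleleCall] = []
        for j in range(lo, hi):
            if rng.random() > config.obs_prob:
                continue
            allele = int(truth.haplotypes[hap_of[mol], j])
            if config.error_rate > 0 and rng.random() < config.error_rate:
                allele = 1 - allele  # biallelic flip
            calls.append(AlleleCall(j + 1, allele, config.quality))
        mol_calls.append(calls)

    # molecule fragments + truth table, ordinals by leftmost position
    molecule_fragments: list[Fragment] = []
    table: list[MoleculeRecord] = []
    for bc in sorted(set(barcode_of.tolist())):
        barcode = f"BX{bc:06d}"
        members = [m for m in range(n_mol) if barcode_of[m] == bc]
        members.sort(key=lambda m: (int(starts[m]), m))
        ordinal = 0
        for m in members:
            calls = mol_calls[m]
            if len(calls) < 2:
                continue
            ordinal += 1
            molecule_fragments.append(
                Fragment(
                    id=f"{barcode}_{ordinal}",
                    origin="molecule",
                    calls=tuple(calls),
                    barcode=barcode,
                    molecule_ordinal=ordinal,
                )
            )
            table.append(
                MoleculeRecord(
                    barcode=barcode,
                    ordinal=ordinal,
                    haplotype=int(hap_of[m]),
                    start=int(starts[m]),
                    end=int(ends[m]),
                    n_calls=len(calls),
                )
            )

    as_barcode_input = [
        Fragment(
            id=f.id, origin="read", calls=f.calls, barcode=f.barcode
        )
        for f in molecule_fragments
    ]
    barcode_fragments = merge_by_barcode(as_barcode_input)
    return SimResult(
        variants=list(variants),
        truth=truth,
        barcode_fragments=barcode_fragments,
        molecule_fragments=molecule_fragments,
        molecule_table=table,
    )


def simulate(config: SimConfig) -> SimResult:
    """Convenience: truth plus fragments from one seeded generator."""
    rng = np.random.default_rng(config.seed)
    variants, truth = generate_truth(config, rng)
    return simulate_fragments(variants, truth, config, rng)


def apply_allele_errors(
    fragments: Sequence[Fragment],
    error_rate: float,
    rng: np.random.Generator,
) -> list[Fragment]:
    """Flip each call's allele independently with the given probability.

    Applying this to an error-free simulation reproduces the generator's
    own per-observed-allele error process, but lets a study hold the
    molecules and observation pattern fixed while varying the error rate
    (common random numbers), so that error-rate comparisons are paired.
    Biallelic codes only.
    """
    if not 0.0 <= error_rate <= 1.0:
        raise ValueError("error_rate must be in [0, 1]")
    out: list[Fragment] = []
    for frag in fragments:
        flips = rng.random(len(frag.calls)) < error_rate
        if not flips.any():
            out.append(frag)
            continue
        calls = tuple(
            AlleleCall(c.variant_index, 1 - c.allele, c.quality) if f else c
            for c, f in zip(frag.calls, flips)
        )
        out.append(
            Fragment(
                id=frag.id, origin=frag.origin, calls=calls,
                barcode=frag.barcode, molecule_ordinal=frag.molecule_ordinal,
            )
        )
    return out


def write_molecule_table(table: Sequence[MoleculeRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("barcode\tordinal\thaplotype\tstart\tend\tn_calls\n")
        for r in table:
            fh.write(
                f"{r.barcode}\t{r.ordinal}\t{r.haplotype}\t{r.start}\t"
                f"{r.end}\t{r.n_calls}\n"
            )


# ---------------------------------------------------------------------------
# SAM/VCF fixture emission (synthetic stand-ins for aligner/caller output)


def emit_fixture_sam_vcf(
    result: SimResult,
    config: SimConfig,
    sam_path: str | Path,
    vcf_path: str | Path,
) -> None:
    """Write a minimal synthetic single-sample VCF and barcoded SAM.

    One 151 bp read is emitted per simulated allele observation, with the
    observed allele substituted at its SNP and every *other* SNP inside
    the read window masked by a base matching neither reference nor
    alternate (so extraction produces exactly the simulated calls).
    Running extraction + barcode merging on these files reproduces the
    simulated barcode fragments.
    """
    variants = result.variants
    G = config.genome_length
    ref = np.full(G + 1, "A", dtype="<U1")  # 1-based; position 0 unused
    by_index: dict[int, VariantSite] = {}
    for v in variants:
        ref[v.position] = v.ref_allele
        by_index[v.index] = v
    pos_sorted = np.asarray([v.position for v in variants])

    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID=sim,length={G}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsample\n")
        for v in variants:
            gt = "/".join(
                ["0"] * (config.ploidy - v.dosage) + ["1"] * v.dosage
            )
            fh.write(
                f"sim\t{v.position}\t.\t{v.ref_allele}\t"
                f"{','.join(v.alt_alleles)}\t.\tPASS\t.\tGT\t{gt}\n"
            )

    read_len = 151
    with open(sam_path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        fh.write(f"@SQ\tSN:sim\tLN:{G}\n")
        lines = []
        for frag in result.molecule_fragments:
            for i, call in enumerate(frag.calls):
                site = by_index[call.variant_index]
                start = max(1, min(site.position - read_len // 2, G - read_len + 1))
                seq = list(ref[start : start + read_len])
                quals = [config.quality] * read_len
                lo = np.searchsorted(pos_sorted, start)
                hi = np.searchsorted(pos_sorted, start + read_len - 1, side="right")
                for j in range(lo, hi):
                    v = variants[j]
                    off = v.position - start
                    if v.index == call.variant_index:
                        seq[off] = site.alleles[call.allele]
                        quals[off] = call.quality
                    else:
                        used = set(v.alleles)
                        seq[off] = next(n for n in _NUCS if n not in used)
                qname = f"{frag.id}:{i}"
                qual_str = "".join(chr(min(q, 93) + 33) for q in quals)
                lines.append(
                    (
                        start,
                        f"{qname}\t0\tsim\t{start}\t60\t{read_len}M\t*\t0\t0\t"
                        f"{''.join(seq)}\t{qual_str}\tBX:Z:{frag.barcode}",
                    )
                )
        for _, line in sorted(lines, key=lambda x: x[0]):
            fh.write(line + "\n")
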