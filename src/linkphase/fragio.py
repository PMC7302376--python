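"""Variant and fragment models with fragment-file input/output.

Haplotype assembly operates on *fragments*: compact records of the alleles
a read (or a barcode, or a single DNA molecule) was observed to carry at
heterozygous SNP sites.  This module

* loads heterozygous SNPs from a polyploid single-sample VCF,
* extracts per-read fragments from aligned linked reads (SAM/BAM carrying
  the 10X-style ``BX`` barcode tag),
* merges read fragments sharing a barcode into long barcode-specific
  fragments, and
* reads and writes the four text fragment-file dialects exchanged between
  pipeline stages (per-read without/with barcode, barcode-specific and
  molecule-specific).

Variant indices are 1-based ordinals over the retained heterozygous SNPs;
allele codes are integers (0 = reference, 1..3 = alternates); qualities are
Phred scores, encoded Phred-33 in fragment files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pysam

logger = logging.getLogger(__name__)

_NUCS = ("A", "C", "G", "T")
_MAX_ALLELES = 4  # allele codes 0..3


class FragmentFormatError(ValueError):
    """Malformed fragment file or VCF content."""


class PloidyMismatchError(ValueError):
    """Genotype arity in the VCF disagrees with the configured ploidy."""


class FragmentFileDialect(str, Enum):
    """Layout of the optional third column of a fragment file.

    ``short_read``        no third column (plain per-read fragments)
    ``barcoded``          per-read fragments with the raw barcode
    ``barcode_specific``  one fragment per barcode (after merging)
    ``molecule_specific`` one fragment per molecule, named ``<barcode>_<n>``
    """

    SHORT_READ = "short_read"
    BARCODED = "barcoded"
    BARCODE_SPECIFIC = "barcode_specific"
    MOLECULE_SPECIFIC = "molecule_specific"


_DIALECT_ORIGIN = {
    FragmentFileDialect.SHORT_READ: "read",
    FragmentFileDialect.BARCODED: "read",
    FragmentFileDialect.BARCODE_SPECIFIC: "barcode",
    FragmentFileDialect.MOLECULE_SPECIFIC: "molecule",
}

#: Sentinel written in the barcode column for fragments without a barcode.
NO_BARCODE = "-"


@dataclass(frozen=True, slots=True)
class VariantSite:
    """One retained heterozygous SNP.

    ``index`` is the 1-based ordinal among retained sites (consecutive after
    filtering); ``position`` the 1-based genomic coordinate; ``dosage`` the
    number of alternate alleles in the genotype of this (biallelic) site.
    """

    index: int
    position: int
    ref_allele: str
    alt_alleles: tuple[str, ...]
    dosage: int
    chrom: str | None = None

    @property
    def alleles(self) -> tuple[str, ...]:
        return (self.ref_allele, *self.alt_alleles)


@dataclass(frozen=True, slots=True)
class AlleleCall:
    """An observed allele at one variant site."""

    variant_index: int
    allele: int
    quality: int

    def __post_init__(self) -> None:
        if not 0 <= self.allele < _MAX_ALLELES:
            raise ValueError(f"allele code {self.allele} outside 0..3")
        if self.variant_index < 1:
            raise ValueError("variant_index is 1-based")
        if self.quality < 0:
            raise ValueError("negative Phred quality")


@dataclass(frozen=True, slots=True)
class Fragment:
    """An ordered set of allele calls with provenance.

    ``origin`` is ``read``, ``barcode`` or ``molecule``; molecule fragments
    carry both ``barcode`` and a 1-based ``molecule_ordinal``.
    """

    id: str
    origin: str
    calls: tuple[AlleleCall, ...]
    barcode: str | None = None
    molecule_ordinal: int | None = None

    def __post_init__(self) -> None:
        if self.origin not in ("read", "barcode", "molecule"):
            raise ValueError(f"unknown fragment origin {self.origin!r}")
        if not self.calls:
            raise ValueError("fragment has no calls")
        idx = [c.variant_index for c in self.calls]
        if idx != sorted(idx) or len(set(idx)) != len(idx):
            raise ValueError("calls must be sorted with unique variant indices")
        if self.origin == "molecule" and (
            self.barcode is None or self.molecule_ordinal is None
        ):
            raise ValueError("molecule fragments need barcode and ordinal")

    @property
    def variant_indices(self) -> tuple[int, ...]:
        return tuple(c.variant_index for c in self.calls)

    @property
    def first_index(self) -> int:
        return self.calls[0].variant_index

    @property
    def last_index(self) -> int:
        return self.calls[-1].variant_index


# ---------------------------------------------------------------------------
# VCF loading


def load_heterozygous_variants(
    vcf_source: str | Path, ploidy: int | None = None
) -> list[VariantSite]:
    """Load heterozygous SNPs from a single-sample VCF, renumbered 1..M.

    Homozygous sites, non-SNP records, sites with more than three alternate
    alleles and sites with missing genotypes are dropped.  The genotype
    arity of every retained record must equal ``ploidy`` (inferred from the
    first usable record when not given).
    """
    vf = pysam.VariantFile(str(vcf_source))
    samples = list(vf.header.samples)
    if len(samples) != 1:
        raise FragmentFormatError(
            f"expected a single-sample VCF, found {len(samples)} samples"
        )
    sites: list[VariantSite] = []
    last_pos: tuple[str | None, int] | None = None
    for rec in vf:
        try:
            gt = rec.samples[0].get("GT")
        except Exception as exc:  # pragma: no cover - defensive
            raise FragmentFormatError(
                f"malformed VCF record at {rec.chrom}:{rec.pos}: {exc}"
            ) from exc
        if gt is None or any(a is None for a in gt):
            continue
        alts = tuple(a for a in (rec.alts or ()) if a is not None)
        if len(rec.ref) != 1 or rec.ref not in _NUCS:
            continue
        if not alts or any(len(a) != 1 or a not in _NUCS for a in alts):
            continue
        if len(alts) > _MAX_ALLELES - 1:
            logger.warning(
                "site %s:%d has >3 alternate alleles; dropped", rec.chrom, rec.pos
            )
            continue
        if ploidy is None:
            ploidy = len(gt)
        if len(gt) != ploidy:
            raise PloidyMismatchError(
                f"GT arity {len(gt)} at {rec.chrom}:{rec.pos} != ploidy {ploidy}"
            )
        n_alt = sum(1 for a in gt if a != 0)
        if n_alt == 0 or n_alt == ploidy:
            continue  # homozygous: uninformative for phasing
        key = (rec.chrom, rec.pos)
        if last_pos is not None and key[0] == last_pos[0] and rec.pos <= last_pos[1]:
            logger.warning(
                "non-increasing position %s:%d; record dropped", rec.chrom, rec.pos
            )
            continue
        last_pos = key
        sites.append(
            VariantSite(
                index=len(sites) + 1,
                position=rec.pos,
                ref_allele=rec.ref,
                alt_alleles=alts,
                dosage=n_alt,
                chrom=rec.chrom,
            )
        )
    return sites


# ---------------------------------------------------------------------------
# Read extraction


def _resolve_site(
    candidates: Sequence[tuple[int, int]],
) -> tuple[int, int] | None:
    """Resolve conflicting allele observations at one site.

    ``candidates`` is a list of ``(allele, quality)``.  The highest-quality
    allele wins; a tie between *different* alleles at the top quality drops
    the site entirely (returns ``None``).
    """
    best_q = max(q for _, q in candidates)
    top = {a for a, q in candidates if q == best_q}
    if len(top) > 1:
        return None
    return (top.pop(), best_q)


def extract_read_fragments(
    sam_source: str | Path,
    variants: Sequence[VariantSite],
    *,
    keep_single_barcoded: bool = True,
    counters: dict | None = None,
) -> list[Fragment]:
    """Extract one fragment per read pair from an alignment file.

    The base at each covered SNP is compared against the site's reference
    and alternate alleles; bases matching none of them are skipped.  Mates
    (records sharing a query name) are merged into a single fragment, with
    same-site conflicts resolved by base quality.  Fragments with fewer
    than two calls are discarded unless they carry a barcode and
    ``keep_single_barcoded`` is true (such reads become informative once
    merged by barcode; set the flag false for the strict behaviour of
    filtering before merging).
    """
    by_pos: dict[tuple[str | None, int], VariantSite] = {}
    for v in variants:
        by_pos[(v.chrom, v.position)] = v

    stats = {
        "skipped_unmapped": 0,
        "skipped_secondary": 0,
        "skipped_supplementary": 0,
        "records_used": 0,
        "dropped_lt2_calls": 0,
        "fragments": 0,
    }
    pending: dict[str, dict] = {}
    with pysam.AlignmentFile(str(sam_source), require_index=False) as af:
        for rec in af:
            if rec.is_unmapped:
                stats["skipped_unmapped"] += 1
                continue
            if rec.is_secondary:
                stats["skipped_secondary"] += 1
                continue
            if rec.is_supplementary:
                stats["skipped_supplementary"] += 1
                continue
            seq = rec.query_sequence
            if seq is None:
                continue
            quals = rec.query_qualities
            entry = pending.setdefault(
                rec.query_name, {"sites": {}, "barcode": None}
            )
            if rec.has_tag("BX"):
                entry["barcode"] = str(rec.get_tag("BX"))
            for qpos, rpos in rec.get_aligned_pairs(matches_only=True):
                site = by_pos.get((rec.reference_name, rpos + 1))
                if site is None:
                    site = by_pos.get((None, rpos + 1))
                if site is None:
                    continue
                base = seq[qpos].upper()
                try:
                    allele = site.alleles.index(base)
                except ValueError:
                    continue  # matches neither ref nor any alt
                q = int(quals[qpos]) if quals is not None else 0
                entry["sites"].setdefault(site.index, []).append((allele, q))
            stats["records_used"] += 1

    fragments: list[Fragment] = []
    for name, entry in pending.items():
        calls = []
        for idx in sorted(entry["sites"]):
            resolved = _resolve_site(entry["sites"][idx])
            if resolved is not None:
                calls.append(AlleleCall(idx, resolved[0], resolved[1]))
        if not calls:
            continue
        if len(calls) < 2 and not (entry["barcode"] and keep_single_barcoded):
            stats["dropped_lt2_calls"] += 1
            continue
        fragments.append(
            Fragment(
                id=name, origin="read", calls=tuple(calls), barcode=entry["barcode"]
            )
        )
    stats["fragments"] = len(fragments)
    if counters is not None:
        counters.update(stats)
    logger.info("extracted %d read fragments (%s)", len(fragments), stats)
    return fragments


def merge_by_barcode(fragments: Iterable[Fragment]) -> list[Fragment]:
    """Unite all calls of fragments sharing a barcode into one fragment.

    At a site with conflicting alleles the higher-quality call wins and an
    equal-quality conflict drops the site.  Merged fragments with fewer
    than two calls are discarded.  Fragments without a barcode pass through
    unchanged (provided they keep >= 2 calls).  Idempotent and independent
    of input order within a barcode.
    """
    grouped: dict[str, dict[int, list[tuple[int, int]]]] = {}
    passthrough: list[Fragment] = []
    for frag in fragments:
        if frag.barcode is None:
            if len(frag.calls) >= 2:
                passthrough.append(frag)
            continue
        sites = grouped.setdefault(frag.barcode, {})
        for call in frag.calls:
            sites.setdefault(call.variant_index, []).append(
                (call.allele, call.quality)
            )
    merged: list[Fragment] = []
    for barcode in sorted(grouped):
        calls = []
        for idx in sorted(grouped[barcode]):
            resolved = _resolve_site(grouped[barcode][idx])
            if resolved is not None:
                calls.append(AlleleCall(idx, resolved[0], resolved[1]))
        if len(calls) < 2:
            continue
        merged.append(
            Fragment(
                id=barcode, origin="barcode", calls=tuple(calls), barcode=barcode
            )
        )
    out = merged + passthrough
    out.sort(key=lambda f: (f.first_index, f.id))
    return out


# ---------------------------------------------------------------------------
# Fragment file I/O


def _split_parts(calls: Sequence[AlleleCall]) -> list[tuple[int, str]]:
    """Group calls into maximal runs of consecutive variant indices."""
    parts: list[tuple[int, str]] = []
    start = calls[0].variant_index
    alleles = [str(calls[0].allele)]
    prev = start
    for c in calls[1:]:
        if c.variant_index == prev + 1:
            alleles.append(str(c.allele))
        else:
            parts.append((start, "".join(alleles)))
            start = c.variant_index
            alleles = [str(c.allele)]
        prev = c.variant_index
    parts.append((start, "".join(alleles)))
    return parts


def format_fragment_line(frag: Fragment, dialect: FragmentFileDialect) -> str:
    parts = _split_parts(frag.calls)
    cols = [str(len(parts)), frag.id]
    if dialect in (FragmentFileDialect.BARCODED, FragmentFileDialect.BARCODE_SPECIFIC):
        cols.append(frag.barcode if frag.barcode is not None else NO_BARCODE)
    elif dialect is FragmentFileDialect.MOLECULE_SPECIFIC:
        cols.append(f"{frag.barcode}_{frag.molecule_ordinal}")
    for start, alleles in parts:
        cols.append(str(start))
        cols.append(alleles)
    cols.append("".join(chr(min(c.quality, 93) + 33) for c in frag.calls))
    return " ".join(cols)


def write_fragment_file(
    fragments: Iterable[Fragment],
    path: str | Path,
    dialect: FragmentFileDialect | str,
) -> None:
    dialect = FragmentFileDialect(dialect)
    with open(path, "w") as fh:
        for frag in fragments:
            fh.write(format_fragment_line(frag, dialect) + "\n")


def parse_fragment_line(
    line: str, dialect: FragmentFileDialect, lineno: int = 0
) -> Fragment:
    tokens = line.split()
    where = f"line {lineno}" if lineno else "line"
    try:
        n_parts = int(tokens[0])
    except (IndexError, ValueError):
        raise FragmentFormatError(f"{where}: missing or non-integer part count")
    frag_id = tokens[1]
    barcode: str | None = None
    ordinal: int | None = None
    pos = 2
    if dialect in (FragmentFileDialect.BARCODED, FragmentFileDialect.BARCODE_SPECIFIC):
        barcode = tokens[pos]
        if barcode == NO_BARCODE:
            barcode = None
        pos += 1
    elif dialect is FragmentFileDialect.MOLECULE_SPECIFIC:
        name = tokens[pos]
        if "_" not in name:
            raise FragmentFormatError(
                f"{where}: molecule column {name!r} lacks '_<ordinal>'"
            )
        barcode, ord_str = name.rsplit("_", 1)
        try:
            ordinal = int(ord_str)
        except ValueError:
            raise FragmentFormatError(f"{where}: non-integer molecule ordinal")
        pos += 1
    if len(tokens) != pos + 2 * n_parts + 1:
        raise FragmentFormatError(
            f"{where}: expected {pos + 2 * n_parts + 1} columns for "
            f"{n_parts} parts, found {len(tokens)}"
        )
    calls: list[AlleleCall] = []
    allele_runs: list[tuple[int, str]] = []
    for p in range(n_parts):
        try:
            start = int(tokens[pos + 2 * p])
        except ValueError:
            raise FragmentFormatError(f"{where}: non-integer part start")
        allele_runs.append((start, tokens[pos + 2 * p + 1]))
    qual_str = tokens[-1]
    total = sum(len(a) for _, a in allele_runs)
    if len(qual_str) != total:
        raise FragmentFormatError(
            f"{where}: quality string length {len(qual_str)} != "
            f"{total} alleles"
        )
    qi = 0
    for start, alleles in allele_runs:
        for offset, ch in enumerate(alleles):
            if ch not in "0123":
                raise FragmentFormatError(f"{where}: bad allele code {ch!r}")
            calls.append(
                AlleleCall(start + offset, int(ch), ord(qual_str[qi]) - 33)
            )
            qi += 1
    return Fragment(
        id=frag_id,
        origin=_DIALECT_ORIGIN[dialect],
        calls=tuple(calls),
        barcode=barcode,
        molecule_ordinal=ordinal,
    )


def read_fragment_file(
    path: str | Path, dialect: FragmentFileDialect | str
) -> list[Fragment]:
    dialect = FragmentFileDialect(dialect)
    fragments: list[Fragment] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fragments.append(parse_fragment_line(line, dialect, lineno))
    return fragments
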