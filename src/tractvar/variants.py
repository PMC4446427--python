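"""Variant normalization and assignment to tracts.

Variants are normalized (multi-allelics split, parsimony-trimmed,
indels left-aligned) and then placed into tract coordinates on the
purine strand.  Single-base substitutions become positional ``tract_SNV``
(positions 1..n) or ``flank_SNV`` (positions 0 and n+1) events; 1-bp
indels of the tract base that change the run length by one without
altering the flanking base composition are replication *slippage*
(``slippage_plus``/``slippage_minus``); every other insertion/deletion of
1-200 bp touching the tract or its flanks is an *indel*
(``indel_ins``/``indel_del``).  Slippage and indels are disjoint
categories: the two analyses never double-count an event.

Indel classification is decided by apply-and-rescan: the edit is applied
to the local reference window and the containing maximal run re-measured,
so the slippage definition is operational rather than pattern-based.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

from .tracts import COMPLEMENT, Tract, _RUN_RE, _normalize_seq

logger = logging.getLogger(__name__)

MAX_INDEL_SIZE = 200

SNV_CATEGORIES = ("tract_SNV", "flank_SNV")
SLIPPAGE_CATEGORIES = ("slippage_plus", "slippage_minus")
INDEL_CATEGORIES = ("indel_ins", "indel_del")


@dataclass(frozen=True, slots=True)
class VariantRecord:
    """A normalized biallelic variant (1-based VCF position)."""

    chrom: str
    pos: int
    ref: str
    alt: str

    @property
    def vtype(self) -> str:
        if len(self.ref) == 1 and len(self.alt) == 1:
            return "SNV"
        return "INS" if len(self.alt) > len(self.ref) else "DEL"

    @property
    def size(self) -> int:
        return abs(len(self.alt) - len(self.ref))


@dataclass(frozen=True, slots=True)
class TractVariantAssignment:
    """A variant placed in a tract's purine-strand coordinate system.

    ``position`` is the purine-strand base position p (SNVs) or the
    insertion junction j (insertions, including slippage_plus); deletions
    carry a location class in ``location`` instead.  ``substitution`` is
    the (from, to) pair on the purine strand for SNVs.
    """

    tract: Tract
    category: str
    position: int | None = None
    location: str | None = None
    substitution: tuple[str, str] | None = None
    extends_tract: bool = False
    cpg_context: bool = False
    indel_size: int = 0


class ReferenceAccessor:
    """Uniform fetch over dict-of-strings or pyfaidx.Fasta references."""

    def __init__(self, source):
        self._src = source

    def length(self, chrom: str) -> int:
        return len(self._src[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """0-based half-open slice, clamped to the sequence, uppercased."""
        start = max(0, start)
        end = min(self.length(chrom), end)
        if end <= start:
            return ""
        return str(self._src[chrom][start:end]).upper()

    def contigs(self) -> list[str]:
        return list(self._src.keys())


def _as_accessor(reference) -> ReferenceAccessor:
    return reference if isinstance(reference, ReferenceAccessor) else ReferenceAccessor(reference)


# ---------------------------------------------------------------------------
# Normalization


def normalize_variants(
    records: Iterable[tuple[str, int, str, str | Sequence[str]]],
    reference,
) -> list[VariantRecord]:
    """Split, trim and left-align raw VCF entries.

    ``records`` yields (chrom, pos, ref, alt-or-alts).  Multi-allelic
    entries are split into biallelic records; shared prefixes/suffixes are
    trimmed to the parsimonious representation and indels are shifted to
    their leftmost equivalent placement.  Records whose REF does not match
    the reference, non-variants, and symbolic/breakend alleles are dropped
    with a logged warning.
    """
    ref_acc = _as_accessor(reference)
    contigs = set(ref_acc.contigs())
    out: list[VariantRecord] = []
    for chrom, pos, ref, alts in records:
        if chrom not in contigs:
            raise KeyError(f"contig {chrom!r} absent from the reference")
        if isinstance(alts, str):
            alts = [alts]
        ref = ref.upper()
        if ref_acc.fetch(chrom, pos - 1, pos - 1 + len(ref)) != ref:
            logger.warning("REF mismatch at %s:%d %s; record dropped", chrom, pos, ref)
            continue
        for alt in alts:
            alt = alt.upper()
            if alt == ref:
                continue
            if not alt or any(c not in "ACGTN" for c in alt):
                logger.warning("unsupported ALT %r at %s:%d; dropped", alt, chrom, pos)
                continue
            out.append(_normalize_one(chrom, pos, ref, alt, ref_acc))
    return [v for v in out if v is not None]


def _normalize_one(
    chrom: str, pos: int, ref: str, alt: str, ref_acc: ReferenceAccessor
) -> VariantRecord | None:
    """Parsimony-trim and left-align one biallelic record."""
    # right-trim, extending left through the reference when an allele empties
    while ref and alt and ref[-1] == alt[-1]:
        if len(ref) == 1 and len(alt) == 1:
            return None  # non-variant
        ref, alt = ref[:-1], alt[:-1]
        if not ref or not alt:
            if pos == 1:
                base = "N"
            else:
                base = ref_acc.fetch(chrom, pos - 2, pos - 1)
            pos -= 1
            ref, alt = base + ref, base + alt
    # left-trim down to one shared anchor base
    while len(ref) >= 2 and len(alt) >= 2 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return VariantRecord(chrom, pos, ref, alt)


def dedupe_variants(records: Iterable[VariantRecord]) -> list[VariantRecord]:
    """Unique on (chrom, pos, ref, alt), sorted by coordinate."""
    return sorted(set(records), key=lambda v: (v.chrom, v.pos, v.ref, v.alt))


def read_vcf(path: str) -> Iterator[tuple[str, int, str, tuple[str, ...]]]:
    """Yield raw (chrom, pos, ref, alts) tuples from a VCF via cyvcf2."""
    from cyvcf2 import VCF

    vcf = VCF(path)
    for rec in vcf:
        yield rec.CHROM, rec.POS, rec.REF, tuple(rec.ALT)
    vcf.close()


# ---------------------------------------------------------------------------
# SNV assignment


def _purine(base: str, strand: str) -> str:
    return base if strand == "+" else COMPLEMENT.get(base, "N")


def assign_snv(tract: Tract, v: VariantRecord) -> TractVariantAssignment | None:
    """Place an SNV in tract coordinates, or None when it lies outside.

    Eligible forward-strand coordinates are [start-1, end]: the tract body
    plus the two flank bases.  The substitution is expressed on the purine
    strand (complemented for '-' tracts).
    """
    if v.vtype != "SNV" or v.chrom != tract.chrom:
        return None
    coord = v.pos - 1
    if coord < tract.start - 1 or coord > tract.end:
        return None
    p = tract.purine_position(coord)
    sub = (_purine(v.ref, tract.purine_strand), _purine(v.alt, tract.purine_strand))
    base = tract.tract_class  # purine-strand tract base is A or G
    cpg = tract.tract_class == "G" and p == 1 and tract.flank5 == "C"
    if 1 <= p <= tract.n:
        return TractVariantAssignment(
            tract, "tract_SNV", position=p, substitution=sub, cpg_context=cpg
        )
    return TractVariantAssignment(
        tract,
        "flank_SNV",
        position=p,
        substitution=sub,
        extends_tract=(sub[1] == base),
    )


# ---------------------------------------------------------------------------
# Indel assignment (apply-and-rescan)


def _insertion_junction(tract: Tract, anchor0: int) -> int | None:
    """Purine-strand junction j for an insertion between anchor0 and anchor0+1.

    j = 0 is between the 5' flank and the first tract base, j = n+1
    between the 3' flank and the base after it.  Returns None when the
    junction lies outside 0..n+1.
    """
    if tract.purine_strand == "+":
        j = anchor0 - tract.start + 1
    else:
        j = tract.end - anchor0 - 1
    return j if 0 <= j <= tract.n + 1 else None


def _deletion_location(tract: Tract, span: tuple[int, int]) -> str | None:
    """Location class of a deleted span relative to the tract (purine strand)."""
    ds, de = span
    if ds < tract.end and de > tract.start:
        return "in_tract"
    before_coord = tract.start - 1 if tract.purine_strand == "+" else tract.end
    after_coord = tract.end if tract.purine_strand == "+" else tract.start - 1
    if ds <= before_coord < de:
        return "before_tract"
    if ds <= after_coord < de:
        return "after_tract"
    return None


def assign_indel(
    tract: Tract, v: VariantRecord, reference
) -> TractVariantAssignment | None:
    """Classify a normalized indel against a tract.

    The edit is applied to the reference window around the tract and the
    containing maximal run re-scanned.  A 1-bp edit that leaves a run of
    the same base with length n±1 and both flanking base identities
    unchanged is slippage; any other edit whose span or breakpoint touches
    the tract body or its flank bases is an indel.
    """
    if v.vtype not in ("INS", "DEL") or v.chrom != tract.chrom:
        return None
    if not (1 <= v.size <= MAX_INDEL_SIZE):
        return None
    ref_acc = _as_accessor(reference)
    anchor0 = v.pos - 1  # 0-based coordinate of the shared anchor base

    if v.vtype == "INS":
        junction = _insertion_junction(tract, anchor0)
        if junction is None:
            return None
    else:
        span = (anchor0 + 1, anchor0 + 1 + v.size)
        location = _deletion_location(tract, span)
        if location is None:
            return None

    if v.size == 1 and _is_slippage(tract, v, ref_acc, anchor0):
        if v.vtype == "INS":
            return TractVariantAssignment(
                tract, "slippage_plus", position=junction, indel_size=1
            )
        return TractVariantAssignment(
            tract, "slippage_minus", location="in_tract", indel_size=1
        )
    if v.vtype == "INS":
        return TractVariantAssignment(
            tract, "indel_ins", position=junction, indel_size=v.size
        )
    return TractVariantAssignment(
        tract, "indel_del", location=location, indel_size=v.size
    )


def _is_slippage(
    tract: Tract, v: VariantRecord, ref_acc: ReferenceAccessor, anchor0: int
) -> bool:
    """Apply the 1-bp edit locally and test for a same-base n±1 run with
    unchanged flanking base identities."""
    pad = MAX_INDEL_SIZE + 2
    while True:
        ws = max(0, tract.start - pad)
        we = min(ref_acc.length(tract.chrom), tract.end + pad)
        if (anchor0 + 1 + v.size <= we and anchor0 >= ws) or (
            ws == 0 and we == ref_acc.length(tract.chrom)
        ):
            break
        logger.info("enlarging rescan window for %s:%d", v.chrom, v.pos)
        pad *= 2
    window = _normalize_seq(ref_acc.fetch(tract.chrom, ws, we))
    run_base = window[tract.start - ws]
    left_base = window[tract.start - ws - 1] if tract.start - ws - 1 >= 0 else None
    right_base = window[tract.end - ws] if tract.end - ws < len(window) else None

    a = anchor0 - ws
    if v.vtype == "INS":
        ins = v.alt[1:]
        edited = window[: a + 1] + ins + window[a + 1 :]

        def image(x: int) -> int:
            return x if x <= a else x + len(ins)

        target_len = tract.n + 1
    else:
        ds, de = a + 1, a + 1 + v.size
        edited = window[:ds] + window[de:]

        def image(x: int) -> int:
            if x < ds:
                return x
            return ds if x < de else x - v.size

        target_len = tract.n - 1

    ts, te = image(tract.start - ws), image(tract.end - ws)
    best = None
    for m in _RUN_RE.finditer(edited):
        if m.group(0)[0] != run_base:
            continue
        if m.end() > ts and m.start() < max(te, ts + 1):
            ov = min(m.end(), te) - max(m.start(), ts)
            if best is None or ov > best[2]:
                best = (m.start(), m.end(), ov)
    if best is None:
        return False
    rs, re_ = best[0], best[1]
    if re_ - rs != target_len:
        return False
    new_left = edited[rs - 1] if rs - 1 >= 0 else None
    new_right = edited[re_] if re_ < len(edited) else None
    return new_left == left_base and new_right == right_base


# ---------------------------------------------------------------------------
# Joint mapping


def map_variants(
    tracts: Sequence[Tract],
    variants: Sequence[VariantRecord],
    reference,
) -> list[TractVariantAssignment]:
    """Assign coordinate-sorted variants to coordinate-sorted tracts.

    Every (tract, variant) pair whose coordinates can interact is tested
    exactly once; output is ordered by tract coordinate.  Raises on
    unsorted input.
    """
    _check_sorted([(t.chrom, t.start) for t in tracts], "tracts")
    _check_sorted([(v.chrom, v.pos) for v in variants], "variants")
    ref_acc = _as_accessor(reference)

    by_chrom: dict[str, list[Tract]] = {}
    for t in tracts:
        by_chrom.setdefault(t.chrom, []).append(t)
    starts = {c: np.array([t.start for t in ts]) for c, ts in by_chrom.items()}

    out: list[TractVariantAssignment] = []
    reach = MAX_INDEL_SIZE + 14  # max tract length + flanks + indel span
    for v in variants:
        ts = by_chrom.get(v.chrom)
        if not ts:
            continue
        v_end = v.pos - 1 + max(len(v.ref), 1) + 1
        lo = int(np.searchsorted(starts[v.chrom], v.pos - 1 - reach, side="left"))
        hi = int(np.searchsorted(starts[v.chrom], v_end + 2, side="right"))
        for t in ts[lo:hi]:
            if v.vtype == "SNV":
                a = assign_snv(t, v)
            else:
                a = assign_indel(t, v, ref_acc)
            if a is not None:
                out.append(a)
    out.sort(key=lambda a: (a.tract.chrom, a.tract.start, a.tract.end))
    return out


def _check_sorted(keys: list[tuple[str, int]], what: str) -> None:
    for prev, cur in zip(keys, keys[1:]):
        if cur < prev:
            raise ValueError(f"{what} are not coordinate-sorted at {cur}")


def assignments_to_frame(assignments: Iterable[TractVariantAssignment]):
    """Tidy table of assignments (one row per event)."""
    import pandas as pd

    rows = []
    for a in assignments:
        t = a.tract
        rows.append(
            (
                t.chrom, t.start, t.end, t.n, t.tract_class, t.purine_strand,
                t.flank5, t.flank3, a.category,
                a.position if a.position is not None else -1,
                a.location or "",
                f"{a.substitution[0]}>{a.substitution[1]}" if a.substitution else "",
                a.extends_tract, a.cpg_context, a.indel_size,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "start", "end", "n", "tract_class", "purine_strand",
            "flank5", "flank3", "category", "position", "location",
            "substitution", "extends_tract", "cpg_context", "indel_size",
        ],
    )
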