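"""Pairwise genome alignment and variant calling for near-identical genomes.

Two chloroplast genomes of the same genus differ by a handful of SNPs and
short InDels, so a full dynamic-programming alignment is unnecessary: unique
shared k-mers anchor a collinear chain and only the short windows between
anchors are aligned with an affine-gap global aligner (Gotoh).  Variants are
then read off the alignment, with InDels left-normalized to the VCF
convention and annotated with their genic/intergenic context.

Scoring is fixed for reproducibility: match +1, mismatch -2, gap open -4,
gap extend -1 (a gap of length L costs 4 + L).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .genome_io import AnnotationFeature, CircularGenome

MATCH = 1
MISMATCH = -2
GAP_OPEN = 4  # penalty for opening a gap, on top of per-base extension
GAP_EXT = 1

_NEG = -(10**9)

# CIGAR-style ops: '=' match, 'X' mismatch, 'I' insertion (qry-only),
# 'D' deletion (ref-only)
Ops = list[tuple[str, int]]


class DivergenceError(ValueError):
    """Genomes too divergent for anchored alignment."""


@dataclass
class PairwiseAlignment:
    """Global alignment of two genomes as a run-length op list."""

    ref_id: str
    qry_id: str
    ref_seq: str
    qry_seq: str
    ops: Ops
    params: dict = field(default_factory=dict)

    @property
    def identity(self) -> float:
        cols = sum(n for _, n in self.ops)
        match = sum(n for op, n in self.ops if op == "=")
        return match / cols if cols else 1.0

    def op_counts(self) -> dict[str, int]:
        out = {"=": 0, "X": 0, "I": 0, "D": 0}
        for op, n in self.ops:
            out[op] += n
        return out

    def validate(self) -> None:
        c = self.op_counts()
        if c["="] + c["X"] + c["D"] != len(self.ref_seq):
            raise ValueError("ops do not tile the reference")
        if c["="] + c["X"] + c["I"] != len(self.qry_seq):
            raise ValueError("ops do not tile the query")
        # reconstruct both sequences from the columns
        i = j = 0
        for op, n in self.ops:
            if op in "=X":
                r, q = self.ref_seq[i : i + n], self.qry_seq[j : j + n]
                if op == "=" and r != q:
                    raise ValueError("match run differs between genomes")
                if op == "X" and any(a == b for a, b in zip(r, q)):
                    raise ValueError("mismatch run contains equal bases")
                i += n
                j += n
            elif op == "D":
                i += n
            else:
                j += n

    def aligned_rows(self) -> tuple[str, str]:
        """Explicit gapped rows (ref, qry)."""
        r_parts, q_parts = [], []
        i = j = 0
        for op, n in self.ops:
            if op in "=X":
                r_parts.append(self.ref_seq[i : i + n])
                q_parts.append(self.qry_seq[j : j + n])
                i += n
                j += n
            elif op == "D":
                r_parts.append(self.ref_seq[i : i + n])
                q_parts.append("-" * n)
                i += n
            else:
                r_parts.append("-" * n)
                q_parts.append(self.qry_seq[j : j + n])
                j += n
        return "".join(r_parts), "".join(q_parts)


def _push(ops: Ops, op: str, n: int) -> None:
    if n <= 0:
        return
    if ops and ops[-1][0] == op:
        ops[-1] = (op, ops[-1][1] + n)
    else:
        ops.append((op, n))


def _match_ops(a: str, b: str) -> Ops:
    """Column ops for two equal-length ungapped strings."""
    ops: Ops = []
    for x, y in zip(a, b):
        _push(ops, "=" if x == y else "X", 1)
    return ops


# ---------------------------------------------------------------------------
# Affine-gap global alignment (Gotoh), vectorized over rows
# ---------------------------------------------------------------------------


def gotoh_align(a: str, b: str, max_cells: int = 30_000_000) -> Ops:
    """Optimal global alignment of two strings under the fixed affine scoring.

    Returns ops with ``a`` as reference.  DP matrices are kept in full for
    traceback, so the product of lengths is capped at ``max_cells``.
    """
    if not a and not b:
        return []
    if not a:
        return [("I", len(b))]
    if not b:
        return [("D", len(a))]
    m, n = len(a), len(b)
    if (m + 1) * (n + 1) > max_cells:
        raise MemoryError(
            f"alignment window {m}x{n} too large; increase anchor density "
            "or reduce max_window"
        )
    av = np.frombuffer(a.encode(), dtype=np.uint8)
    bv = np.frombuffer(b.encode(), dtype=np.uint8)
    sub = np.where(av[:, None] == bv[None, :], MATCH, MISMATCH).astype(np.int32)

    M = np.full((m + 1, n + 1), _NEG, dtype=np.int32)
    Ix = np.full((m + 1, n + 1), _NEG, dtype=np.int32)  # gap in b (consumes a)
    Iy = np.full((m + 1, n + 1), _NEG, dtype=np.int32)  # gap in a (consumes b)
    M[0, 0] = 0
    js = np.arange(1, n + 1, dtype=np.int32)
    Iy[0, 1:] = -GAP_OPEN - GAP_EXT * js
    is_ = np.arange(1, m + 1, dtype=np.int32)
    Ix[1:, 0] = -GAP_OPEN - GAP_EXT * is_

    open_cost = GAP_OPEN + GAP_EXT
    for i in range(1, m + 1):
        prevM, prevIx, prevIy = M[i - 1], Ix[i - 1], Iy[i - 1]
        best_prev = np.maximum(np.maximum(prevM, prevIx), prevIy)
        M[i, 1:] = best_prev[:-1] + sub[i - 1]
        Ix[i, 1:] = np.maximum(
            np.maximum(prevM[1:], prevIy[1:]) - open_cost, prevIx[1:] - GAP_EXT
        )
        # Iy has an in-row dependency; closed form via running maximum:
        # Iy[i, j] = max_{k<j} max(M,Ix)[i, k] - GAP_OPEN - (j-k)*GAP_EXT
        rowMI = np.maximum(M[i], Ix[i])
        c = rowMI + GAP_EXT * np.arange(n + 1, dtype=np.int32)
        run = np.maximum.accumulate(c[:-1])
        Iy[i, 1:] = run - GAP_OPEN - GAP_EXT * js

    # traceback
    ops_rev: list[str] = []
    i, j = m, n
    state = int(np.argmax([M[i, j], Ix[i, j], Iy[i, j]]))
    while i > 0 or j > 0:
        if state == 0:  # M
            prev = (M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1])
            ops_rev.append("=" if a[i - 1] == b[j - 1] else "X")
            state = int(np.argmax(prev))
            i -= 1
            j -= 1
        elif state == 1:  # Ix: consumes a[i-1]
            ops_rev.append("D")
            if i > 1 or j > 0:
                if Ix[i, j] == Ix[i - 1, j] - GAP_EXT:
                    state = 1
                elif Ix[i, j] == M[i - 1, j] - open_cost:
                    state = 0
                else:
                    state = 2
            i -= 1
        else:  # Iy: consumes b[j-1]
            ops_rev.append("I")
            if j > 1 or i > 0:
                if Iy[i, j] == Iy[i, j - 1] - GAP_EXT:
                    state = 2
                elif Iy[i, j] == M[i, j - 1] - open_cost:
                    state = 0
                else:
                    state = 1
            j -= 1
        if i == 0 and j > 0:
            state = 2
        elif j == 0 and i > 0:
            state = 1
    ops: Ops = []
    for op in reversed(ops_rev):
        _push(ops, op, 1)
    return ops


# ---------------------------------------------------------------------------
# Anchored global alignment
# ---------------------------------------------------------------------------


def _unique_kmers(seq: str, k: int) -> dict[str, int]:
    pos: dict[str, int] = {}
    dup: set[str] = set()
    for i in range(len(seq) - k + 1):
        km = seq[i : i + k]
        if km in dup:
            continue
        if km in pos:
            del pos[km]
            dup.add(km)
        else:
            pos[km] = i
    return pos


def _anchor_chain(ref: str, qry: str, k: int) -> list[tuple[int, int, int]]:
    """Collinear chain of (ref_pos, qry_pos, length) from shared unique k-mers."""
    rk = _unique_kmers(ref, k)
    qk = _unique_kmers(qry, k)
    pairs = sorted((r, qk[km]) for km, r in rk.items() if km in qk)
    if not pairs:
        return []
    # longest increasing subsequence in qry coordinate (patience, O(n log n))
    import bisect

    tails: list[int] = []  # qry values
    tails_idx: list[int] = []
    parent = [-1] * len(pairs)
    for idx, (_, q) in enumerate(pairs):
        pos = bisect.bisect_left(tails, q)
        if pos == len(tails):
            tails.append(q)
            tails_idx.append(idx)
        else:
            tails[pos] = q
            tails_idx[pos] = idx
        parent[idx] = tails_idx[pos - 1] if pos > 0 else -1
    chain_idx = []
    cur = tails_idx[-1]
    while cur != -1:
        chain_idx.append(cur)
        cur = parent[cur]
    chain_idx.reverse()
    chain = [pairs[i] for i in chain_idx]
    # merge k-mers into maximal non-overlapping anchors; drop anchors that
    # would overlap their predecessor off-diagonal
    anchors: list[tuple[int, int, int]] = []
    for r, q in chain:
        if anchors:
            pr, pq, pl = anchors[-1]
            if r - pr == q - pq and r <= pr + pl:  # same diagonal, contiguous
                anchors[-1] = (pr, pq, max(pl, r - pr + k))
                continue
            if r < pr + pl or q < pq + pl:  # crossing/overlapping: skip
                continue
        anchors.append((r, q, k))
    return anchors


def align_genomes(
    ref: CircularGenome | str,
    qry: CircularGenome | str,
    k: int = 21,
    max_window: int = 20000,
) -> PairwiseAlignment:
    """Anchored affine-gap global alignment of two near-identical genomes.

    Unique shared k-mers are chained collinearly (longest increasing
    subsequence by reference order); windows between consecutive anchors are
    aligned with :func:`gotoh_align`.  Genomes should be canonically rotated
    first so that their coordinates are comparable.
    """
    ref_seq = ref.sequence if isinstance(ref, CircularGenome) else ref
    qry_seq = qry.sequence if isinstance(qry, CircularGenome) else qry
    ref_id = ref.id if isinstance(ref, CircularGenome) else "ref"
    qry_id = qry.id if isinstance(qry, CircularGenome) else "qry"

    if ref_seq == qry_seq:
        aln = PairwiseAlignment(
            ref_id, qry_id, ref_seq, qry_seq, [("=", len(ref_seq))],
            params={"k": k, "max_window": max_window},
        )
        return aln

    if min(len(ref_seq), len(qry_seq)) <= max(200, 4 * k):
        # too short for useful anchoring: full DP is cheap here
        aln = PairwiseAlignment(
            ref_id, qry_id, ref_seq, qry_seq, gotoh_align(ref_seq, qry_seq),
            params={"k": k, "max_window": max_window},
        )
        aln.validate()
        return aln

    anchors = _anchor_chain(ref_seq, qry_seq, k)
    covered = sum(length for _, _, length in anchors)
    if covered < 0.5 * len(ref_seq):
        raise DivergenceError(
            f"anchor chain covers only {covered} of {len(ref_seq)} reference bases; "
            "genomes too divergent for anchored alignment"
        )
    ops: Ops = []
    r_prev = q_prev = 0
    for r, q, length in anchors + [(len(ref_seq), len(qry_seq), 0)]:
        wr, wq = ref_seq[r_prev:r], qry_seq[q_prev:q]
        if len(wr) > max_window or len(wq) > max_window:
            raise ValueError(
                f"inter-anchor window of {max(len(wr), len(wq))} bp exceeds "
                f"max_window={max_window}; increase max_window or decrease k"
            )
        if wr or wq:
            if len(wr) == len(wq):
                window_ops = (
                    _match_ops(wr, wq) if wr != wq else [("=", len(wr))]
                )
                # equal-length windows with many mismatches still deserve DP
                if sum(n for op, n in window_ops if op == "X") > 0.3 * max(len(wr), 1):
                    window_ops = gotoh_align(wr, wq)
            else:
                window_ops = gotoh_align(wr, wq)
            for op, n in window_ops:
                _push(ops, op, n)
        if length:
            _push(ops, "=", length)
        r_prev, q_prev = r + length, q + length
    aln = PairwiseAlignment(
        ref_id, qry_id, ref_seq, qry_seq, ops,
        params={
            "k": k,
            "max_window": max_window,
            "scoring": f"match {MATCH}, mismatch {MISMATCH}, "
            f"gap open -{GAP_OPEN}, gap extend -{GAP_EXT}",
        },
    )
    aln.validate()
    return aln


# ---------------------------------------------------------------------------
# Variant calling
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Variant:
    """A left-normalized difference between reference and query.

    ``ref_pos`` is the 1-based VCF position; for InDels the alleles include
    the anchor base.  ``length`` is |len(alt) - len(ref)| for InDels, the run
    length for SNP/MNP.
    """

    ref_pos: int
    type: str  # SNP, MNP, insertion, deletion
    ref_allele: str
    alt_allele: str
    length: int
    context: str = "unknown"  # genic | intergenic | unknown
    context_detail: str = ""  # gene name, or flanking pair "rpoC2-rps2"
    qry_pos: int = 0  # 1-based position of the event in the query

    @property
    def signed_length(self) -> int:
        if self.type == "insertion":
            return self.length
        if self.type == "deletion":
            return -self.length
        return 0


def _left_normalize_indel(
    ref_seq: str, pos0: int, inserted: str | None, deleted_len: int
) -> tuple[int, str]:
    """Shift an InDel to its lowest equivalent reference position.

    ``pos0`` is the 0-based reference position where the event occurs
    (deletion removes ref[pos0:pos0+deleted_len]; insertion inserts before
    ref[pos0]).  Returns the new position and the (possibly rotated) event
    sequence.
    """
    if inserted is not None:
        s = inserted
        while pos0 > 0 and s and ref_seq[pos0 - 1] == s[-1]:
            s = ref_seq[pos0 - 1] + s[:-1]
            pos0 -= 1
        return pos0, s
    # deletion: rotating requires the base entering from the left to match
    # the base leaving on the right
    end = pos0 + deleted_len
    while pos0 > 0 and ref_seq[pos0 - 1] == ref_seq[end - 1]:
        pos0 -= 1
        end -= 1
    return pos0, ref_seq[pos0:end]


def _annotate(
    variants: list[Variant], features: list[AnnotationFeature], genome_length: int
) -> list[Variant]:
    genes = sorted(
        (f for f in features if f.kind in ("gene", "tRNA", "rRNA")),
        key=lambda f: f.start,
    )
    out = []
    for v in variants:
        start0 = v.ref_pos - 1
        end0 = start0 + max(len(v.ref_allele), 1)
        hit = [g for g in genes if g.overlaps(start0, end0)]
        if hit:
            v = replace(v, context="genic", context_detail=hit[0].name)
        elif genes:
            left = [g for g in genes if g.end <= start0]
            right = [g for g in genes if g.start >= end0]
            lname = (max(left, key=lambda g: g.end) if left else genes[-1]).name
            rname = (min(right, key=lambda g: g.start) if right else genes[0]).name
            v = replace(v, context="intergenic", context_detail=f"{lname}-{rname}")
        out.append(v)
    return out


def call_variants(
    aln: PairwiseAlignment,
    annotation: list[AnnotationFeature] | None = None,
    merge_mnp: bool = True,
) -> list[Variant]:
    """Read variants off a global alignment.

    Adjacent gap columns of one type form a single InDel event; runs of two
    or more adjacent mismatches form an MNP when ``merge_mnp`` is true,
    otherwise individual SNPs.  InDels are left-normalized against the
    reference and reported VCF-style with an anchor base.
    """
    ref, qry = aln.ref_seq, aln.qry_seq
    variants: list[Variant] = []
    i = j = 0
    for op, n in aln.ops:
        if op == "=":
            i += n
            j += n
        elif op == "X":
            if merge_mnp and n >= 2:
                variants.append(
                    Variant(
                        ref_pos=i + 1,
                        type="MNP",
                        ref_allele=ref[i : i + n],
                        alt_allele=qry[j : j + n],
                        length=n,
                        qry_pos=j + 1,
                    )
                )
            else:
                for t in range(n):
                    variants.append(
                        Variant(
                            ref_pos=i + t + 1,
                            type="SNP",
                            ref_allele=ref[i + t],
                            alt_allele=qry[j + t],
                            length=1,
                            qry_pos=j + t + 1,
                        )
                    )
            i += n
            j += n
        elif op == "I":
            ins = qry[j : j + n]
            pos0, ins = _left_normalize_indel(ref, i, ins, 0)
            qshift = i - pos0  # left shift applies equally in qry coordinates
            if pos0 > 0:
                anchor = ref[pos0 - 1]
                variants.append(
                    Variant(
                        ref_pos=pos0,
                        type="insertion",
                        ref_allele=anchor,
                        alt_allele=anchor + ins,
                        length=n,
                        qry_pos=j - qshift,
                    )
                )
            else:  # event at origin: anchor on the following base
                anchor = ref[0]
                variants.append(
                    Variant(
                        ref_pos=1,
                        type="insertion",
                        ref_allele=anchor,
                        alt_allele=ins + anchor,
                        length=n,
                        qry_pos=1,
                    )
                )
            j += n
        else:  # D
            pos0, dele = _left_normalize_indel(ref, i, None, n)
            qshift = i - pos0
            if pos0 > 0:
                anchor = ref[pos0 - 1]
                variants.append(
                    Variant(
                        ref_pos=pos0,
                        type="deletion",
                        ref_allele=anchor + dele,
                        alt_allele=anchor,
                        length=n,
                        qry_pos=j - qshift,
                    )
                )
            else:
                anchor = ref[n] if n < len(ref) else ""
                variants.append(
                    Variant(
                        ref_pos=1,
                        type="deletion",
                        ref_allele=dele + anchor,
                        alt_allele=anchor or dele[0],
                        length=n,
                        qry_pos=1,
                    )
                )
            i += n
    variants.sort(key=lambda v: (v.ref_pos, v.type))
    if annotation:
        variants = _annotate(variants, annotation, len(ref))
    return variants


def decompose_mnps(variants: list[Variant]) -> list[Variant]:
    """Expand MNP events into their constituent SNPs."""
    out: list[Variant] = []
    for v in variants:
        if v.type != "MNP":
            out.append(v)
            continue
        for t, (r, a) in enumerate(zip(v.ref_allele, v.alt_allele)):
            out.append(
                replace(
                    v,
                    ref_pos=v.ref_pos + t,
                    type="SNP",
                    ref_allele=r,
                    alt_allele=a,
                    length=1,
                    qry_pos=v.qry_pos + t,
                )
            )
    out.sort(key=lambda v: (v.ref_pos, v.type))
    return out


def variant_counts(variants: list[Variant]) -> dict[str, int]:
    """SNP/InDel tallies under both MNP conventions."""
    snp = sum(1 for v in variants if v.type == "SNP")
    mnp = sum(1 for v in variants if v.type == "MNP")
    snp_decomposed = snp + sum(v.length for v in variants if v.type == "MNP")
    indel = sum(1 for v in variants if v.type in ("insertion", "deletion"))
    return {
        "snp_events": snp + mnp,  # MNPs counted as single events
        "snp_sites": snp_decomposed,  # MNPs decomposed to per-site SNPs
        "indels": indel,
        "signed_indel_sum": sum(v.signed_length for v in variants),
    }


def gene_variant_scan(
    variants: list[Variant],
    gene_names: list[str],
    features: list[AnnotationFeature],
) -> dict[str, int]:
    """Count variants overlapping each named gene."""
    by_name: dict[str, list[AnnotationFeature]] = {}
    for f in features:
        by_name.setdefault(f.name, []).append(f)
    missing = [g for g in gene_names if g not in by_name]
    if missing:
        raise KeyError(
            f"unknown gene name(s) {missing}; available: {sorted(by_name)}"
        )
    counts = {g: 0 for g in gene_names}
    for g in gene_names:
        for f in by_name[g]:
            for v in variants:
                start0 = v.ref_pos - 1
                end0 = start0 + max(len(v.ref_allele), 1)
                if f.overlaps(start0, end0):
                    counts[g] += 1
    return counts


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------


def write_vcf(
    variants: list[Variant], ref_id: str, ref_length: int, path: str
) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.3\n")
        fh.write(f"##contig=<ID={ref_id},length={ref_length}>\n")
        fh.write(
            '##INFO=<ID=TYPE,Number=1,Type=String,Description="Variant type">\n'
        )
        fh.write(
            '##INFO=<ID=CTX,Number=1,Type=String,Description="Genic context">\n'
        )
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in variants:
            info = f"TYPE={v.type};CTX={v.context}"
            if v.context_detail:
                info += f",{v.context_detail}"
            fh.write(
                f"{ref_id}\t{v.ref_pos}\t.\t{v.ref_allele}\t{v.alt_allele}"
                f"\t.\tPASS\t{info}\n"
            )


def variants_to_table(variants: list[Variant]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "ref_pos": v.ref_pos,
                "type": v.type,
                "ref_allele": v.ref_allele,
                "alt_allele": v.alt_allele,
                "length": v.length,
                "context": v.context,
                "context_detail": v.context_detail,
            }
            for v in variants
        ]
    )
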