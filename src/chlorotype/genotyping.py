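"""In-silico PCR and cytoplasm (cytotype) classification.

A marker is a primer pair with expected per-cytotype product sizes.  PCR is
simulated by locating primer binding sites on both strands of the circular
template (optionally allowing mismatches, with the three 3'-terminal bases
always exact) and measuring the primer-inclusive distance between paired
sites.  Each sample is then called S, N, ambiguous, or no_amplification by
comparing its product sizes to the marker expectations within a sizing
tolerance, and calls are tallied per cultivar.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome_io import CircularGenome, revcomp
from .markers import MarkerDefinition


@dataclass(frozen=True)
class Amplicon:
    marker: str
    genome_id: str
    start: int  # 0-based, canonical coordinates; end may exceed genome length
    end: int
    strand: str

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class CytotypeCall:
    sample_id: str
    amplicon_sizes: dict[str, list[int]]  # marker -> product lengths
    call: str  # S | N | ambiguous | no_amplification
    evidence: dict[str, str] = field(default_factory=dict)  # marker -> matched cytotype


@dataclass
class CohortSummary:
    table: pd.DataFrame  # index: cultivar (+ Total row); columns n_total/n_S/n_N/n_other


# ---------------------------------------------------------------------------
# Primer site search
# ---------------------------------------------------------------------------


def _find_sites(
    hay: str, pattern: str, max_mismatch: int, anchor_3prime: str
) -> list[int]:
    """Start positions where ``pattern`` matches ``hay`` with at most
    ``max_mismatch`` mismatches; the pattern's 3'-terminal 3 bases (at the
    'right' or 'left' end, per ``anchor_3prime``) must match exactly.
    """
    m = len(pattern)
    if m > len(hay):
        return []
    if max_mismatch == 0:
        out = []
        start = 0
        while True:
            idx = hay.find(pattern, start)
            if idx == -1:
                return out
            out.append(idx)
            start = idx + 1
    arr = np.frombuffer(hay.encode(), dtype=np.uint8)
    pat = np.frombuffer(pattern.encode(), dtype=np.uint8)
    npos = len(hay) - m + 1
    mism = np.zeros(npos, dtype=np.int32)
    for k in range(m):
        mism += arr[k : k + npos] != pat[k]
    ok = mism <= max_mismatch
    anchor = range(m - 3, m) if anchor_3prime == "right" else range(0, 3)
    for k in anchor:
        ok &= arr[k : k + npos] == pat[k]
    return list(np.flatnonzero(ok))


def insilico_pcr(
    genome: CircularGenome,
    fwd: str,
    rev: str,
    max_mismatch: int = 0,
    max_product: int = 2000,
    marker_name: str = "",
) -> list[Amplicon]:
    """All predicted PCR products of a primer pair on a circular template.

    Product length is outer-edge to outer-edge, i.e. inclusive of both
    primer footprints; primer footprints may not overlap.  Products spanning
    the circular origin are found by scanning the doubled sequence.  Both
    template orientations are searched.  Results are sorted by length.
    """
    fwd, rev = fwd.upper(), rev.upper()
    seq = genome.sequence
    n = len(seq)
    hay = seq + seq if genome.circular else seq
    amps: list[Amplicon] = []

    def scan(p_left: str, p_right_rc: str, strand: str) -> None:
        # p_left anneals to the minus strand and extends rightward from its
        # site; the partner's site appears as p_right_rc on the plus strand.
        left_sites = _find_sites(hay, p_left, max_mismatch, anchor_3prime="right")
        right_sites = _find_sites(hay, p_right_rc, max_mismatch, anchor_3prime="left")
        left_sites = [i for i in left_sites if i < n]
        for i in left_sites:
            for j in right_sites:
                if j < i + len(p_left):
                    continue
                product = j + len(p_right_rc) - i
                if product > max_product or (genome.circular and product > n):
                    continue
                amps.append(
                    Amplicon(
                        marker=marker_name,
                        genome_id=genome.id,
                        start=i,
                        end=i + product,
                        strand=strand,
                    )
                )

    scan(fwd, revcomp(rev), "+")
    scan(rev, revcomp(fwd), "-")
    # the same physical product found in both orientations is one molecule
    uniq = {}
    for a in amps:
        key = (a.start % n, a.length)
        if key not in uniq:
            uniq[key] = a
    return sorted(uniq.values(), key=lambda a: (a.length, a.start))


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------


def _marker_vote(
    sizes: list[int], marker: MarkerDefinition, tolerance_bp: int
) -> str | None:
    """Cytotype supported by this marker's products, 'ambiguous', or None
    (no product)."""
    if not sizes:
        return None
    tol = tolerance_bp if tolerance_bp is not None else marker.tolerance_bp
    matched: set[str] = set()
    for size in sizes:
        hits = {
            ct for ct, exp in marker.expected.items() if abs(size - exp) <= tol
        }
        matched |= hits
    if len(matched) == 1:
        return next(iter(matched))
    if len(matched) > 1:
        return "ambiguous"
    return "ambiguous"  # product present but matches no expectation


def classify_cytotype(
    sample_genome: CircularGenome,
    markers: list[MarkerDefinition],
    tolerance_bp: int | None = None,
    max_mismatch: int = 0,
) -> CytotypeCall:
    """Call a sample's cytotype from in-silico amplicon sizes.

    The call is a cytotype only if every amplifying marker supports that same
    cytotype; mixed or unmatched sizes give ``ambiguous``; no product from
    any marker gives ``no_amplification``.
    """
    if not markers:
        raise ValueError("at least one marker definition is required")
    sizes: dict[str, list[int]] = {}
    votes: dict[str, str] = {}
    for marker in markers:
        amps = insilico_pcr(
            sample_genome,
            marker.fwd,
            marker.rev,
            max_mismatch=max_mismatch,
            marker_name=marker.name,
        )
        sizes[marker.name] = [a.length for a in amps]
        vote = _marker_vote(
            sizes[marker.name],
            marker,
            marker.tolerance_bp if tolerance_bp is None else tolerance_bp,
        )
        if vote is not None:
            votes[marker.name] = vote
    if not votes:
        call = "no_amplification"
    elif "ambiguous" in votes.values():
        call = "ambiguous"
    elif len(set(votes.values())) == 1:
        call = next(iter(votes.values()))
    else:
        call = "ambiguous"
    return CytotypeCall(
        sample_id=sample_genome.id, amplicon_sizes=sizes, call=call, evidence=votes
    )


def summarize_cohort(
    calls: list[CytotypeCall], manifest: dict[str, str]
) -> CohortSummary:
    """Per-cultivar S/N/other tallies with a grand-total row.

    ``manifest`` maps sample id -> cultivar; every call must be mapped.
    """
    rows: dict[str, dict[str, int]] = {}
    for call in calls:
        if call.sample_id not in manifest:
            raise KeyError(f"sample {call.sample_id!r} missing from manifest")
        cultivar = manifest[call.sample_id]
        row = rows.setdefault(
            cultivar, {"n_total": 0, "n_S": 0, "n_N": 0, "n_other": 0}
        )
        row["n_total"] += 1
        if call.call == "S":
            row["n_S"] += 1
        elif call.call == "N":
            row["n_N"] += 1
        else:
            row["n_other"] += 1
    df = pd.DataFrame.from_dict(rows, orient="index").astype(int)
    if df.empty:
        df = pd.DataFrame(columns=["n_total", "n_S", "n_N", "n_other"]).astype(int)
    df.loc["Total"] = df.sum()
    df.index.name = "cultivar"
    return CohortSummary(table=df)


def read_manifest(path: str) -> dict[str, str]:
    """Sample manifest TSV with columns sample_id, cultivar[, genome_path]."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in df.columns or "cultivar" not in df.columns:
        raise ValueError(f"{path}: manifest needs sample_id and cultivar columns")
    return dict(zip(df["sample_id"], df["cultivar"]))


def calls_to_table(calls: list[CytotypeCall]) -> pd.DataFrame:
    markers = sorted({m for c in calls for m in c.amplicon_sizes})
    rows = []
    for c in calls:
        row = {"sample_id": c.sample_id, "call": c.call}
        for m in markers:
            row[f"{m}_bp"] = ",".join(map(str, c.amplicon_sizes.get(m, []))) or "-"
        rows.append(row)
    return pd.DataFrame(rows)
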