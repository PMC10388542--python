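"""Synthetic chloroplast genomes, cytotype pairs and cohorts for testing.

The generator emulates the statistical structure of a real CMS study at desk
scale: a circular quadripartite genome (LSC + IRb + SSC + revcomp(IRb)) with
gene-like annotation features, one or more tandem-repeat copy-number loci in
named intergenic spacers that differ between the sterile (S) and fertile (N)
cytotype, primer-compatible flanks around each locus, a sprinkling of SNPs
between cytotypes, and multi-sample cohorts of uniform per-cultivar
cytotype.  Every emitted artifact is paired with a truth record so each
pipeline stage can be checked against what was planted.

All randomness flows from a single seed through named substreams, so the
same spec yields byte-identical output regardless of which features are
generated.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .genome_io import AnnotationFeature, CircularGenome, revcomp, write_fasta

_SUBSTREAMS = {
    "backbone": 0,
    "genes": 1,
    "markers": 2,
    "snps": 3,
    "cohort": 4,
    "species": 5,
}

# published diagnostic primer pairs for sorghum cytoplasm typing; the
# generator plants compatible binding sites so in-silico PCR reproduces the
# field-validated product sizes
CP01_FWD = "AGAGACCCCGTTTACCCCTA"
CP01_REV = "TTGTTCCGATGGAACCTTCT"
CP02_FWD = "CGTGTTTGAAATTTTGGGTCT"
CP02_REV = "CGAGTCTGTTGTCATTCTACTGC"


@dataclass
class CnvSpec:
    """A tandem-repeat copy-number locus planted in an intergenic spacer."""

    name: str
    spacer: tuple[str, str]  # flanking gene names, e.g. ("rpoC2", "rps2")
    unit_len: int
    copies: dict[str, int]  # cytotype -> copy number
    fwd_primer: str | None = None
    rev_primer: str | None = None
    amplicon_s: int | None = None  # desired product size in the S cytotype
    unit: str | None = None  # explicit unit sequence; random if None

    def __post_init__(self) -> None:
        if self.unit_len < 1:
            raise ValueError("unit_len must be >= 1")
        if any(c < 1 for c in self.copies.values()):
            raise ValueError("copy numbers must be >= 1")


@dataclass
class CultivarSpec:
    cultivar: str
    n_plants: int
    cytotype: str

    def __post_init__(self) -> None:
        if self.n_plants < 1:
            raise ValueError("cohort sizes must be positive")


@dataclass
class SyntheticSpec:
    seed: int = 42
    lsc_len: int = 8000
    ir_len: int = 2500
    ssc_len: int = 1200
    gc: float = 0.385
    gene_size_range: tuple[int, int] = (300, 900)
    cnv_loci: list[CnvSpec] = field(default_factory=list)
    snp_rate: float = 19 / 140644  # per-site SNP probability between cytotypes
    private_snp_rate: float = 0.0  # within-cultivar neutral variation
    cohort: list[CultivarSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        if min(self.lsc_len, self.ir_len, self.ssc_len) <= 0:
            raise ValueError("segment lengths must be positive")


# Six-cultivar cohort mirroring a typical released-cultivar survey: three
# cultivars fixed for the sterile cytoplasm, three for the fertile one.
DEFAULT_COHORT = [
    CultivarSpec("Nampoongchal", 195, "N"),
    CultivarSpec("Donganme", 170, "S"),
    CultivarSpec("Sodamchal", 236, "S"),
    CultivarSpec("Hwanggeumchal", 313, "N"),
    CultivarSpec("Bareme", 95, "S"),
    CultivarSpec("Noeulchal", 95, "N"),
]


def default_cnv_loci() -> list[CnvSpec]:
    return [
        CnvSpec(
            name="cp_01",
            spacer=("rpoC2", "rps2"),
            unit_len=28,
            copies={"S": 2, "N": 1},
            fwd_primer=CP01_FWD,
            rev_primer=CP01_REV,
            amplicon_s=270,
        ),
        CnvSpec(
            name="cp_02",
            spacer=("cemA", "petA"),
            unit_len=22,
            copies={"S": 2, "N": 1},
            fwd_primer=CP02_FWD,
            rev_primer=CP02_REV,
            amplicon_s=265,
        ),
    ]


def demo_spec(seed: int = 42) -> SyntheticSpec:
    """The default desk-scale study: two CNV markers and a six-cultivar cohort."""
    return SyntheticSpec(
        seed=seed, cnv_loci=default_cnv_loci(), cohort=list(DEFAULT_COHORT)
    )


@dataclass
class TruthRecord:
    structure: dict  # cytotype -> {lsc, irb, ssc, ira} intervals
    cnv_loci: list[dict]
    snps: list[dict]
    cytotypes: dict[str, str] = field(default_factory=dict)  # sample -> cytotype

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=list)


# ---------------------------------------------------------------------------
# Genome pair generation
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

_LSC_GENES = ["psbA", "atpA", "rpoC2", "rps2", "rbcL", "cemA", "petA", "psaA", "psaB"]
_IR_GENES = ["rpl2", "rrn16"]
_SSC_GENES = ["ndhD", "ndhF"]


def _rng(spec_seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([spec_seed, _SUBSTREAMS[stream]])


def _random_dna(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=length, p=p)
    return _BASES[idx].tobytes().decode()


def _random_unit(rng: np.random.Generator, length: int, gc: float) -> str:
    while True:
        u = _random_dna(rng, length, gc)
        # primitive and not homopolymeric
        if len(set(u)) >= 2 and all(
            u != u[:d] * (length // d)
            for d in range(1, length)
            if length % d == 0
        ):
            return u


def generate_genome_pair(
    spec: SyntheticSpec,
) -> tuple[CircularGenome, CircularGenome, TruthRecord]:
    """Build the S-type and N-type template genomes plus their truth record.

    The linear layout is LSC + IRb + SSC + IRa with IRa = revcomp(IRb); each
    CNV locus sits in its named LSC spacer as [fwd-primer site, pad, tandem
    units, pad, reverse-complemented rev-primer site], sized so the S-type
    product matches ``amplicon_s`` when primers are given.  Between-cytotype
    SNPs are placed outside marker spacers.
    """
    rng_b = _rng(spec.seed, "backbone")
    rng_g = _rng(spec.seed, "genes")
    rng_m = _rng(spec.seed, "markers")
    rng_s = _rng(spec.seed, "snps")

    cnv_by_spacer: dict[tuple[str, str], CnvSpec] = {}
    for cnv in spec.cnv_loci:
        if cnv.spacer in cnv_by_spacer:
            raise ValueError(f"two CNV loci share spacer {cnv.spacer}")
        if cnv.spacer[0] not in _LSC_GENES or cnv.spacer[1] not in _LSC_GENES:
            raise ValueError(
                f"CNV locus {cnv.name} requests intergenic placement in unknown "
                f"spacer {cnv.spacer}; available genes: {_LSC_GENES}"
            )
        cnv_by_spacer[cnv.spacer] = cnv

    cytotypes = sorted({ct for cnv in spec.cnv_loci for ct in cnv.copies} or {"S", "N"})

    # --- shared backbone pieces -------------------------------------------
    lo, hi = spec.gene_size_range
    gene_seqs = {g: _random_dna(rng_g, int(rng_g.integers(lo, hi + 1)), spec.gc)
                 for g in _LSC_GENES}
    # IR and SSC genes scaled to their (much shorter) segments
    ir_hi = max(lo, spec.ir_len // 4)
    ssc_hi = max(100, (spec.ssc_len - 400) // 3)
    for g in _IR_GENES:
        gene_seqs[g] = _random_dna(
            rng_g, int(rng_g.integers(min(lo, ir_hi), ir_hi + 1)), spec.gc
        )
    for g in _SSC_GENES:
        gene_seqs[g] = _random_dna(
            rng_g, int(rng_g.integers(100, ssc_hi + 1)), spec.gc
        )

    # marker spacers (per cytotype) and their planted truth
    marker_parts: dict[tuple[str, str], dict[str, str]] = {}
    cnv_truth: list[dict] = []
    for spacer, cnv in cnv_by_spacer.items():
        unit = (cnv.unit or _random_unit(rng_m, cnv.unit_len, spec.gc)).upper()
        if len(unit) != cnv.unit_len:
            raise ValueError(f"CNV {cnv.name}: unit length mismatch")
        fwd = (cnv.fwd_primer or _random_dna(rng_m, 20, 0.5)).upper()
        rev = (cnv.rev_primer or _random_dna(rng_m, 20, 0.5)).upper()
        max_copies = max(cnv.copies.values())
        if cnv.amplicon_s is not None:
            pads = cnv.amplicon_s - len(fwd) - len(rev) - max_copies * cnv.unit_len
            if pads < 2:
                raise ValueError(
                    f"CNV {cnv.name}: amplicon_s too small for primers and units"
                )
        else:
            pads = 60
        pad_left = _random_dna(rng_m, pads // 2, spec.gc)
        pad_right = _random_dna(rng_m, pads - pads // 2, spec.gc)
        margin = _random_dna(rng_m, 25, spec.gc)  # outside the amplicon
        per_ct = {}
        for ct in cytotypes:
            copies = cnv.copies.get(ct, 1)
            per_ct[ct] = (
                margin + fwd + pad_left + unit * copies + pad_right
                + revcomp(rev) + margin
            )
        marker_parts[spacer] = per_ct
        cnv_truth.append(
            {
                "name": cnv.name,
                "spacer": list(spacer),
                "unit": unit,
                "unit_len": cnv.unit_len,
                "copies": dict(cnv.copies),
                "fwd": fwd,
                "rev": rev,
                "amplicons": {
                    ct: len(fwd) + len(pad_left) + cnv.copies.get(ct, 1) * cnv.unit_len
                    + len(pad_right) + len(rev)
                    for ct in cytotypes
                },
            }
        )

    # --- LSC layout: spacer, gene, spacer, gene ... spacer -----------------
    n_lsc_spacers = len(_LSC_GENES) + 1
    fixed = sum(len(gene_seqs[g]) for g in _LSC_GENES)
    fixed += sum(
        len(next(iter(per_ct.values()))) for per_ct in marker_parts.values()
    )  # marker spacers sized by their longest cytotype below; adjust later
    # marker spacer lengths differ by cytotype; budget the LSC on the largest
    free = spec.lsc_len - fixed
    n_plain = n_lsc_spacers - len(marker_parts)
    if free < 10 * n_plain:
        raise ValueError("lsc_len too small for the requested genes and CNV loci")
    cuts = np.sort(rng_b.choice(np.arange(1, free), size=n_plain - 1, replace=False))
    plain_lens = np.diff(np.concatenate([[0], cuts, [free]])).astype(int)
    plain_spacers = [_random_dna(rng_b, int(l), spec.gc) for l in plain_lens]

    # assemble LSC parts in order; marker spacers keyed by preceding gene
    def lsc_parts(ct: str) -> list[tuple[str, str, str]]:
        """(kind, name, seq) with kind in gene|spacer|marker."""
        parts: list[tuple[str, str, str]] = []
        plain_iter = iter(plain_spacers)
        parts.append(("spacer", "lsc_start", next(plain_iter)))
        for gi, g in enumerate(_LSC_GENES):
            parts.append(("gene", g, gene_seqs[g]))
            nxt = _LSC_GENES[gi + 1] if gi + 1 < len(_LSC_GENES) else None
            key = (g, nxt)
            if nxt and key in marker_parts:
                parts.append(("marker", f"{g}-{nxt}", marker_parts[key][ct]))
            else:
                parts.append(("spacer", f"{g}-{nxt or 'end'}", next(plain_iter)))
        return parts

    # --- IRb and SSC -------------------------------------------------------
    ir_genes_len = sum(len(gene_seqs[g]) for g in _IR_GENES)
    ndhh_irb = 400  # ndhH fragment inside IRb; remainder in SSC
    ir_free = spec.ir_len - ir_genes_len
    if ir_free < 3 * 10 + ndhh_irb:
        raise ValueError("ir_len too small for IR genes")
    ir_cuts = np.sort(rng_b.choice(np.arange(1, ir_free), size=2, replace=False))
    ir_sp = np.diff(np.concatenate([[0], ir_cuts, [ir_free]])).astype(int)
    irb_seq = (
        _random_dna(rng_b, int(ir_sp[0]), spec.gc)
        + gene_seqs[_IR_GENES[0]]
        + _random_dna(rng_b, int(ir_sp[1]), spec.gc)
        + gene_seqs[_IR_GENES[1]]
        + _random_dna(rng_b, int(ir_sp[2]), spec.gc)
    )
    irb_gene_offsets = {
        _IR_GENES[0]: (int(ir_sp[0]), int(ir_sp[0]) + len(gene_seqs[_IR_GENES[0]])),
        _IR_GENES[1]: (
            int(ir_sp[0]) + len(gene_seqs[_IR_GENES[0]]) + int(ir_sp[1]),
            int(ir_sp[0]) + len(gene_seqs[_IR_GENES[0]]) + int(ir_sp[1])
            + len(gene_seqs[_IR_GENES[1]]),
        ),
    }

    ssc_genes_len = sum(len(gene_seqs[g]) for g in _SSC_GENES)
    ndhh_ssc = 300
    ssc_free = spec.ssc_len - ssc_genes_len - ndhh_ssc
    if ssc_free < 3 * 5:
        raise ValueError("ssc_len too small for SSC genes")
    ssc_cuts = np.sort(rng_b.choice(np.arange(1, ssc_free), size=2, replace=False))
    ssc_sp = np.diff(np.concatenate([[0], ssc_cuts, [ssc_free]])).astype(int)
    ssc_seq = (
        _random_dna(rng_b, ndhh_ssc, spec.gc)  # tail of ndhH
        + _random_dna(rng_b, int(ssc_sp[0]), spec.gc)
        + gene_seqs[_SSC_GENES[0]]
        + _random_dna(rng_b, int(ssc_sp[1]), spec.gc)
        + gene_seqs[_SSC_GENES[1]]
        + _random_dna(rng_b, int(ssc_sp[2]), spec.gc)
    )
    ssc_gene_offsets = {}
    off = ndhh_ssc + int(ssc_sp[0])
    ssc_gene_offsets[_SSC_GENES[0]] = (off, off + len(gene_seqs[_SSC_GENES[0]]))
    off += len(gene_seqs[_SSC_GENES[0]]) + int(ssc_sp[1])
    ssc_gene_offsets[_SSC_GENES[1]] = (off, off + len(gene_seqs[_SSC_GENES[1]]))

    # pin the IR boundaries: the planted repeats must not be extensible by
    # chance matches, so the single-copy bases flanking each IR junction are
    # forced to break complementarity
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}

    def _break_pairing(piece: str, end_base_of: str) -> str:
        # last base of `piece` must not pair with `end_base_of`
        if piece[-1] != comp[end_base_of]:
            return piece
        for b in "ACGT":
            if b != comp[end_base_of]:
                return piece[:-1] + b
        raise AssertionError

    # first LSC base 'A' plus a non-'T' last base makes the assembled strand
    # the canonical one (its linearization starts 'A...', the reverse
    # candidate starts with the complement of the last base, which is not
    # 'A'), so emitted coordinates equal canonical coordinates
    plain_spacers[0] = "A" + plain_spacers[0][1:]
    lsc_first = plain_spacers[0][0]
    plain_spacers[-1] = _break_pairing(plain_spacers[-1], lsc_first)
    ssc_seq = _break_pairing(ssc_seq, ssc_seq[0])

    # --- between-cytotype SNPs (applied to every cytotype but the first) ---
    # positions indexed on the concatenation of shared plain pieces
    snp_truth: list[dict] = []

    def assemble(ct: str) -> tuple[str, list[AnnotationFeature], dict]:
        feats: list[AnnotationFeature] = []
        pos = 0
        pieces: list[str] = []
        marker_intervals = {}
        for kind, name, seq in lsc_parts(ct):
            if kind == "gene":
                feats.append(AnnotationFeature(name, "gene", pos, pos + len(seq)))
            elif kind == "marker":
                marker_intervals[name] = (pos, pos + len(seq))
            pieces.append(seq)
            pos += len(seq)
        lsc_len_ct = pos
        irb_start = pos
        for g, (s, e) in irb_gene_offsets.items():
            feats.append(AnnotationFeature(g, "gene", irb_start + s, irb_start + e))
        pieces.append(irb_seq)
        pos += len(irb_seq)
        ssc_start = pos
        feats.append(
            AnnotationFeature("ndhH", "gene", ssc_start - ndhh_irb, ssc_start + ndhh_ssc)
        )
        for g, (s, e) in ssc_gene_offsets.items():
            feats.append(AnnotationFeature(g, "gene", ssc_start + s, ssc_start + e))
        pieces.append(ssc_seq)
        pos += len(ssc_seq)
        ira_start = pos
        pieces.append(revcomp(irb_seq))
        for g, (s, e) in irb_gene_offsets.items():
            feats.append(
                AnnotationFeature(
                    g, "gene",
                    ira_start + len(irb_seq) - e,
                    ira_start + len(irb_seq) - s,
                    strand="-",
                )
            )
        seq = "".join(pieces)
        layout = {
            "lsc": (0, lsc_len_ct),
            "irb": (irb_start, ssc_start),
            "ssc": (ssc_start, ira_start),
            "ira": (ira_start, len(seq)),
            "markers": marker_intervals,
        }
        feats.sort(key=lambda f: (f.start, f.end, f.name))
        return seq, feats, layout

    base_ct = cytotypes[0]
    genomes: dict[str, CircularGenome] = {}
    layouts: dict[str, dict] = {}
    seqs: dict[str, str] = {}
    for ct in cytotypes:
        seq, feats, layout = assemble(ct)
        seqs[ct] = seq
        layouts[ct] = layout
        genomes[ct] = CircularGenome(
            id=f"synthetic_{ct}", sequence=seq, features=feats, source="synthetic"
        )

    # SNPs between cytotypes: drawn on the base cytotype's coordinates,
    # outside marker spacers and outside the IRa mirror (mutations applied
    # to IRb propagate there to keep the repeat exact)
    if spec.snp_rate > 0 and len(cytotypes) > 1:
        base_layout = layouts[base_ct]
        n_linear = base_layout["ira"][0]  # LSC+IRb+SSC
        forbidden = [iv for iv in base_layout["markers"].values()]
        draws = rng_s.random(n_linear) < spec.snp_rate
        positions = [
            p
            for p in np.flatnonzero(draws)
            if not any(s <= p < e for s, e in forbidden)
        ]
        for ct in cytotypes[1:]:
            # map base-coordinate position to this cytotype's coordinates:
            # offsets shift only past marker spacers
            shifted = []
            for p in positions:
                delta = 0
                for mk, (s, e) in layouts[base_ct]["markers"].items():
                    s2, e2 = layouts[ct]["markers"][mk]
                    if p >= e:
                        delta += (e2 - s2) - (e - s)
                shifted.append(p + delta)
            seq_list = list(seqs[ct])
            for p_base, p_ct in zip(positions, shifted):
                ref_base = seq_list[p_ct]
                alt = {"A": "G", "G": "A", "C": "T", "T": "C"}[ref_base]
                in_irb = (
                    layouts[ct]["irb"][0] <= p_ct < layouts[ct]["irb"][1]
                )
                seq_list[p_ct] = alt
                if in_irb:  # mirror into IRa to keep IR exact
                    irb_s = layouts[ct]["irb"][0]
                    ira_s, ira_e = layouts[ct]["ira"]
                    mirror = ira_e - 1 - (p_ct - irb_s)
                    seq_list[mirror] = revcomp(alt)
                snp_truth.append(
                    {
                        "cytotype": ct,
                        "pos_base_ct": int(p_base),
                        "pos": int(p_ct),
                        "ref": ref_base,
                        "alt": alt,
                    }
                )
            seqs[ct] = "".join(seq_list)
            genomes[ct] = CircularGenome(
                id=genomes[ct].id,
                sequence=seqs[ct],
                features=genomes[ct].features,
                source="synthetic",
            )

    # emit in canonical orientation: the analysis pipeline canonicalizes
    # every genome, and the strand it picks is deterministic, so align the
    # truth record with it (flip coordinates if the other strand wins)
    from .genome_io import canonical_rotation
    from .quadripartite import QuadripartiteStructure, gc_content_percent

    for ct_name in cytotypes:
        g = genomes[ct_name]
        lay = layouts[ct_name]
        n_len = len(g)
        st = QuadripartiteStructure(
            lsc=tuple(lay["lsc"]), irb=tuple(lay["irb"]), ssc=tuple(lay["ssc"]),
            ira=tuple(lay["ira"]), genome_length=n_len,
            gc_percent=gc_content_percent(g.sequence),
        )
        canon = canonical_rotation(g, st)
        if canon.sequence != g.sequence:  # other strand chosen
            L = lay["lsc"][1]
            comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
            lay["markers"] = {
                k: ((L - e) % n_len, (L - e) % n_len + (e - s))
                for k, (s, e) in lay["markers"].items()
            }
            for snp in snp_truth:
                if snp["cytotype"] == ct_name:
                    snp["pos"] = (L - 1 - snp["pos"]) % n_len
                    snp["ref"] = comp[snp["ref"]]
                    snp["alt"] = comp[snp["alt"]]
        genomes[ct_name] = CircularGenome(
            id=g.id, sequence=canon.sequence, features=canon.features,
            source="synthetic",
        )

    truth = TruthRecord(
        structure={
            ct: {k: list(v) for k, v in layouts[ct].items() if k != "markers"}
            for ct in cytotypes
        },
        cnv_loci=cnv_truth,
        snps=snp_truth,
    )
    # conventional ordering: S first when present
    s_ct = "S" if "S" in genomes else cytotypes[0]
    n_ct = "N" if "N" in genomes else cytotypes[-1]
    return genomes[s_ct], genomes[n_ct], truth


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------


def generate_cohort(
    spec: SyntheticSpec,
    pair: tuple[CircularGenome, CircularGenome],
    out_dir: str | None = None,
) -> tuple[list[CircularGenome], dict[str, str], TruthRecord]:
    """One genome per plant, copied from its cultivar's cytotype template.

    With ``private_snp_rate`` > 0 each plant receives independent neutral
    SNPs outside the marker amplicons.  Returns (genomes, manifest, truth);
    when ``out_dir`` is given, per-sample FASTA files and a manifest TSV are
    also written there.
    """
    s_genome, n_genome = pair
    by_ct = {"S": s_genome, "N": n_genome}
    rng = _rng(spec.seed, "cohort")
    genomes: list[CircularGenome] = []
    manifest: dict[str, str] = {}
    cytotypes: dict[str, str] = {}
    for cultivar in spec.cohort:
        template = by_ct[cultivar.cytotype]
        for i in range(1, cultivar.n_plants + 1):
            sid = f"{cultivar.cultivar}_{i:04d}"
            seq = template.sequence
            if spec.private_snp_rate > 0:
                seq_arr = list(seq)
                k = rng.binomial(len(seq), spec.private_snp_rate)
                for p in rng.choice(len(seq), size=k, replace=False):
                    seq_arr[p] = {"A": "G", "G": "A", "C": "T", "T": "C"}[seq_arr[p]]
                seq = "".join(seq_arr)
            genomes.append(
                CircularGenome(
                    id=sid, sequence=seq, features=list(template.features),
                    source="synthetic",
                )
            )
            manifest[sid] = cultivar.cultivar
            cytotypes[sid] = cultivar.cytotype
    truth = TruthRecord(structure={}, cnv_loci=[], snps=[], cytotypes=cytotypes)
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        with open(os.path.join(out_dir, "manifest.tsv"), "w") as fh:
            fh.write("sample_id\tcultivar\tgenome_path\n")
            for g in genomes:
                path = os.path.join(out_dir, f"{g.id}.fasta")
                write_fasta(g, path)
                fh.write(f"{g.id}\t{manifest[g.id]}\t{path}\n")
        truth.to_json(os.path.join(out_dir, "truth.json"))
    return genomes, manifest, truth


# ---------------------------------------------------------------------------
# Species sets for phylogenetics
# ---------------------------------------------------------------------------


def mutate_genome(
    genome: CircularGenome, n_snps: int, rng: np.random.Generator, new_id: str
) -> CircularGenome:
    """Copy of a genome with ``n_snps`` random transition substitutions."""
    seq = list(genome.sequence)
    for p in rng.choice(len(seq), size=n_snps, replace=False):
        seq[p] = {"A": "G", "G": "A", "C": "T", "T": "C", "N": "N"}[seq[p]]
    return CircularGenome(
        id=new_id, sequence="".join(seq), features=list(genome.features),
        source="synthetic",
    )


def generate_species_set(
    spec: SyntheticSpec,
    pair: tuple[CircularGenome, CircularGenome] | None = None,
) -> tuple[dict[str, CircularGenome], dict]:
    """Eight related genomes derived from the S/N pair on a known tree.

    Two sterile-cytoplasm taxa descend unchanged from a common ancestor
    three substitutions away from the S template (so their mutual distance
    is exactly zero), two fertile-cytoplasm taxa differ by one substitution,
    two more fertile relatives and two distant outgroup-like taxa carry
    increasing numbers of private substitutions.  Returns the genomes and a
    truth dict naming the planted sister pairs.
    """
    if pair is None:
        s_genome, n_genome, _ = generate_genome_pair(spec)
    else:
        s_genome, n_genome = pair
    rng = _rng(spec.seed, "species")
    anc_s = mutate_genome(s_genome, 3, rng, "anc_S")
    anc_n = mutate_genome(n_genome, 3, rng, "anc_N")
    anc_bn = mutate_genome(anc_n, 2, rng, "anc_BN")
    taxa = {
        "sterile_A": CircularGenome(
            id="sterile_A", sequence=anc_s.sequence,
            features=list(anc_s.features), source="synthetic",
        ),
        "wild_sister_S": CircularGenome(
            id="wild_sister_S", sequence=anc_s.sequence,
            features=list(anc_s.features), source="synthetic",
        ),
        "fertile_B": CircularGenome(
            id="fertile_B", sequence=anc_bn.sequence,
            features=list(anc_bn.features), source="synthetic",
        ),
        "wild_sister_N": mutate_genome(anc_bn, 1, rng, "wild_sister_N"),
        "relative_1": mutate_genome(anc_n, 6, rng, "relative_1"),
        "relative_2": mutate_genome(anc_n, 8, rng, "relative_2"),
        "outgroup_near": mutate_genome(n_genome, 20, rng, "outgroup_near"),
        "outgroup_far": mutate_genome(n_genome, 35, rng, "outgroup_far"),
    }
    truth = {
        "sister_pairs": [
            ["sterile_A", "wild_sister_S"],
            ["fertile_B", "wild_sister_N"],
        ],
        "zero_distance_pair": ["sterile_A", "wild_sister_S"],
        "one_snp_pair": ["fertile_B", "wild_sister_N"],
    }
    return taxa, truth


# ---------------------------------------------------------------------------
# Spec serialization
# ---------------------------------------------------------------------------


def load_spec(path: str) -> SyntheticSpec:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    cnv = [
        CnvSpec(
            name=c["name"],
            spacer=tuple(c["spacer"]),
            unit_len=int(c["unit_len"]),
            copies={str(k): int(v) for k, v in c["copies"].items()},
            fwd_primer=c.get("fwd_primer"),
            rev_primer=c.get("rev_primer"),
            amplicon_s=c.get("amplicon_s"),
            unit=c.get("unit"),
        )
        for c in raw.get("cnv_loci", [])
    ]
    cohort = [
        CultivarSpec(c["cultivar"], int(c["n_plants"]), str(c["cytotype"]))
        for c in raw.get("cohort", [])
    ]
    kwargs = {
        k: raw[k]
        for k in (
            "seed", "lsc_len", "ir_len", "ssc_len", "gc",
            "snp_rate", "private_snp_rate",
        )
        if k in raw
    }
    if "gene_size_range" in raw:
        kwargs["gene_size_range"] = tuple(raw["gene_size_range"])
    return SyntheticSpec(cnv_loci=cnv, cohort=cohort, **kwargs)
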