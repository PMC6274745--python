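"""Seeded synthetic-data generators with planted ground truth.

Three generators produce every input the pipeline consumes:

* :func:`generate_annotation` — a reference annotation (protein-coding genes
  with 1-10 exons plus a known-lncRNA subset) and an assembled candidate
  annotation in which every positional class and every class code is planted
  a known number of times;
* :func:`generate_sequences` — transcript sequences in which coding-labeled
  transcripts carry a long in-frame ORF sampled from a codon-biased model
  and non-coding transcripts are near-uniform;
* :func:`generate_counts` — NB-distributed fragment counts under the
  2-treatment x 3-timepoint x 6-cow design, with planted log2 fold changes
  and planted lncRNA-mRNA correlation structure within 50 kb.

All generators are driven by a single integer seed through split
SeedSequence streams, so identical configurations give byte-identical
outputs and adding features does not perturb earlier draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .models import AnnotationSet, TranscriptModel, ValidationError
from .positional import PositionalClass


class SizingError(ValidationError):
    """A chromosome is too short to place a requested feature."""


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

DEFAULT_CLASS_MIX = {
    PositionalClass.INTERGENIC_GT1KB: 0.32,
    PositionalClass.EXONIC_OVERLAP_SENSE: 0.10,
    PositionalClass.EXONIC_OVERLAP_ANTISENSE: 0.10,
    PositionalClass.UPSTREAM_1KB_SENSE: 0.08,
    PositionalClass.UPSTREAM_1KB_ANTISENSE: 0.08,
    PositionalClass.DOWNSTREAM_1KB_SENSE: 0.06,
    PositionalClass.DOWNSTREAM_1KB_ANTISENSE: 0.06,
    PositionalClass.INTRONIC_SENSE: 0.06,
    PositionalClass.INTRONIC_ANTISENSE: 0.06,
    PositionalClass.GENE_IN_LNCRNA_INTRON: 0.04,
    PositionalClass.BIDIRECTIONAL_PROMOTER_SHARED: 0.04,
}

TREATMENTS = ("LSO", "SFO")
DAYS = ("D-14", "D+7", "D+28")


@dataclass(frozen=True)
class Design:
    treatments: tuple[str, ...] = TREATMENTS
    days: tuple[str, ...] = DAYS
    cows_per_treatment: int = 6

    @property
    def n_libraries(self) -> int:
        return len(self.treatments) * len(self.days) * self.cows_per_treatment


def _default_planted_lfc() -> list[tuple[str, tuple[str, str, str], float]]:
    return [
        ("LNC0013", ("LSO", "D-14", "D+7"), 1.5),
        ("LNC0014", ("LSO", "D-14", "D+7"), -1.2),
        ("LNC0015", ("LSO", "D+7", "D+28"), 1.2),
        ("LNC0016", ("LSO", "D+7", "D+28"), -1.5),
        ("LNC0017", ("SFO", "D-14", "D+28"), 1.4),
        ("LNC0018", ("SFO", "D-14", "D+28"), -1.4),
        ("LNC0019", ("SFO", "D+7", "D+28"), 1.2),
        ("LNC0020", ("SFO", "D+7", "D+28"), -1.2),
    ]


def _default_planted_cis() -> list[tuple[str, str, float]]:
    high = [(f"LNC{i:04d}", f"G{i:04d}", 0.9) for i in range(1, 7)]
    low = [(f"LNC{i:04d}", f"G{i:04d}", 0.3) for i in range(7, 13)]
    return high + low


@dataclass(frozen=True)
class SimConfig:
    """Configuration of the synthetic study.

    Defaults emulate the study design the pipeline targets: 36 libraries
    from two diets (LSO, SFO) x three biopsy days (D-14, D+7, D+28) x six
    cows per diet, lncRNA candidates planted in all 11 positional classes,
    and cis pairs placed within 50 kb of their partner gene.
    """

    seed: int = 0
    n_chromosomes: int = 4
    chrom_length: int = 3_000_000
    n_coding_genes: int = 40  # standalone genes beyond the per-lncRNA hosts
    n_lncrna: int = 150
    class_mix: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_MIX))
    design: Design = field(default_factory=Design)
    planted_lfc: list = field(default_factory=_default_planted_lfc)
    planted_cis: list = field(default_factory=_default_planted_cis)
    nb_dispersion: float = 0.05
    mean_depth: int = 100_000  # expected fragments per library
    known_fraction: float = 0.4  # known-lncRNA reference doubles as the noncoding training pool
    n_short_decoys: int = 4  # <200 nt transcripts exercising the length filter
    n_code_decoys: int = 6  # per code in {=, c, j}

    def validate(self) -> None:
        if self.nb_dispersion <= 0:
            raise ValidationError("nb_dispersion must be positive")
        for name in ("n_chromosomes", "chrom_length", "n_coding_genes", "n_lncrna", "mean_depth"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        total = sum(self.class_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"class_mix proportions sum to {total}, expected 1")
        if set(self.class_mix) != set(PositionalClass):
            raise ValidationError("class_mix must cover exactly the 11 positional classes")
        if not 0.0 <= self.known_fraction <= 1.0:
            raise ValidationError("known_fraction must be in [0, 1]")
        if self.n_coding_genes < 3 * self.n_code_decoys:
            raise ValidationError(
                "n_coding_genes must be at least 3 * n_code_decoys to host the =/c/j decoys"
            )


# ---------------------------------------------------------------------------
# Truth table
# ---------------------------------------------------------------------------


@dataclass
class TruthTable:
    """Planted ground truth for every generated feature.

    ``features`` holds one row per assembled candidate (positional class,
    expected class code, coding label, known/novel label, cis partner);
    ``genes`` one row per coding gene; ``transcripts`` one row per sequence
    id with its coding label and spliced length.
    """

    features: pd.DataFrame
    genes: pd.DataFrame
    transcripts: pd.DataFrame
    planted_lfc: pd.DataFrame
    planted_cis: pd.DataFrame

    def day_multiplier(self, feature_id: str, treatment: str, day: str) -> float:
        """Linear expression multiplier of a (treatment, day) cell.

        A planted log2FC on contrast (t, dayA, dayB) is realized as a
        2**lfc multiplier at (t, dayB) with dayA at baseline.
        """
        mult = 1.0
        for _, row in self.planted_lfc.iterrows():
            if row["feature_id"] == feature_id and row["treatment"] == treatment and row["dayB"] == day:
                mult *= 2.0 ** row["log2fc"]
        return mult

    def effective_lfc(self, feature_id: str, contrast: tuple[str, str, str]) -> float:
        """Realized log2FC of a contrast given all planted multipliers."""
        t, day_a, day_b = contrast
        return math.log2(
            self.day_multiplier(feature_id, t, day_b) / self.day_multiplier(feature_id, t, day_a)
        )


# ---------------------------------------------------------------------------
# Annotation generator
# ---------------------------------------------------------------------------


def _allocate_classes(mix: dict, n: int) -> list[PositionalClass]:
    """Largest-remainder allocation of n lncRNAs to classes, >=5 per class."""
    order = list(PositionalClass)
    raw = {c: mix[c] * n for c in order}
    counts = {c: int(math.floor(raw[c])) for c in order}
    remainder = n - sum(counts.values())
    by_frac = sorted(order, key=lambda c: (-(raw[c] - counts[c]), c.value))
    for c in by_frac[:remainder]:
        counts[c] += 1
    # enforce the minimum (for classes actually requested) by moving
    # surplus from the largest classes
    for c in order:
        if mix[c] == 0:
            continue
        while counts[c] < 5:
            donor = max(order, key=lambda d: counts[d])
            if counts[donor] <= 5:
                raise ValidationError("n_lncrna too small to plant every class >=5 times")
            counts[donor] -= 1
            counts[c] += 1
    # intergenic first so default cis/lfc ids land on intergenic candidates
    out: list[PositionalClass] = []
    for c in order:
        out.extend([c] * counts[c])
    return out


def _mirror(exons: list[tuple[int, int]], width: int) -> list[tuple[int, int]]:
    return sorted((width - e, width - s) for s, e in exons)


def _gene_exons(rng: np.random.Generator, n_exons: int | None = None) -> list[tuple[int, int]]:
    n = int(n_exons) if n_exons is not None else int(rng.integers(1, 11))
    pos = 0
    exons = []
    for i in range(n):
        if i:
            pos += int(rng.integers(300, 1501))
        length = int(rng.integers(150, 401))
        exons.append((pos, pos + length))
        pos += length
    return exons


def _lnc_length(rng: np.random.Generator, cap: int = 8000) -> int:
    length = int(np.exp(rng.normal(np.log(900), 0.7)))
    return int(min(max(length, 250), cap))


def _lnc_exons(rng: np.random.Generator, total: int, n_exons: int) -> list[tuple[int, int]]:
    if n_exons == 1 or total < 500:
        return [(0, total)]
    first = total // 2
    intron = int(rng.integers(300, 1200))
    return [(0, first), (first + intron, first + intron + (total - first))]


def _other_strand(s: str) -> str:
    return "-" if s == "+" else "+"


def _build_unit(
    cls: PositionalClass, rng: np.random.Generator
) -> tuple[list[tuple[int, int]], str, list[tuple[int, int]], str, int]:
    """Local-coordinate layout of one (host gene, lncRNA) unit.

    Returns (gene_exons, gene_strand, lnc_exons, lnc_strand, unit_width);
    geometry is built for a +-strand gene and mirrored for a - gene.
    """
    gene_strand = "+" if rng.random() < 0.5 else "-"
    local = "+"  # geometry is built for a +-strand gene, then mirrored
    L = _lnc_length(rng)
    gexons = _gene_exons(rng, n_exons=int(rng.integers(2, 7)))

    if cls is PositionalClass.INTERGENIC_GT1KB:
        gap = int(rng.integers(2000, 20001))
        start = gexons[-1][1] + gap
        lexons = [(s + start, e + start) for s, e in _lnc_exons(rng, L, int(rng.integers(1, 3)))]
        lnc_strand = "+" if rng.random() < 0.5 else "-"
    elif cls in (PositionalClass.EXONIC_OVERLAP_SENSE, PositionalClass.EXONIC_OVERLAP_ANTISENSE):
        # single-exon lncRNA overlapping the first gene exon and extending upstream
        overlap = int(rng.integers(20, min(80, gexons[0][1] - gexons[0][0])))
        shift = L - overlap  # how far the unit origin moves to keep coords >= 0
        gexons = [(s + shift, e + shift) for s, e in gexons]
        lexons = [(gexons[0][0] - (L - overlap), gexons[0][0] + overlap)]
        lnc_strand = (
            local if cls is PositionalClass.EXONIC_OVERLAP_SENSE else _other_strand(local)
        )
    elif cls in (
        PositionalClass.UPSTREAM_1KB_SENSE,
        PositionalClass.UPSTREAM_1KB_ANTISENSE,
        PositionalClass.BIDIRECTIONAL_PROMOTER_SHARED,
    ):
        if cls is PositionalClass.UPSTREAM_1KB_ANTISENSE:
            gap = int(rng.integers(550, 951))
            lnc_strand = _other_strand(local)
        elif cls is PositionalClass.BIDIRECTIONAL_PROMOTER_SHARED:
            gap = int(rng.integers(100, 451))
            lnc_strand = _other_strand(local)
        else:
            gap = int(rng.integers(100, 901))
            lnc_strand = local
        shift = L + gap
        gexons = [(s + shift, e + shift) for s, e in gexons]
        lexons = [(s, e) for s, e in _lnc_exons(rng, L, 1)]
    elif cls in (PositionalClass.DOWNSTREAM_1KB_SENSE, PositionalClass.DOWNSTREAM_1KB_ANTISENSE):
        gap = int(rng.integers(100, 901))
        start = gexons[-1][1] + gap
        lexons = [(start, start + L)]
        lnc_strand = (
            local if cls is PositionalClass.DOWNSTREAM_1KB_SENSE else _other_strand(local)
        )
    elif cls in (PositionalClass.INTRONIC_SENSE, PositionalClass.INTRONIC_ANTISENSE):
        L = min(L, 1500)
        pad = 200
        exon1 = (0, int(rng.integers(150, 401)))
        intron_len = L + 2 * pad
        exon2_start = exon1[1] + intron_len
        gexons = [exon1, (exon2_start, exon2_start + int(rng.integers(150, 401)))]
        lexons = [(exon1[1] + pad, exon1[1] + pad + L)]
        lnc_strand = (
            local if cls is PositionalClass.INTRONIC_SENSE else _other_strand(local)
        )
    elif cls is PositionalClass.GENE_IN_LNCRNA_INTRON:
        pad = 300
        gspan = gexons[-1][1] - gexons[0][0]
        exon1_len = max(200, L // 2)
        intron_len = gspan + 2 * pad
        lexons = [
            (0, exon1_len),
            (exon1_len + intron_len, exon1_len + intron_len + max(200, L - exon1_len)),
        ]
        gexons = [(s + exon1_len + pad, e + exon1_len + pad) for s, e in gexons]
        lnc_strand = "+" if rng.random() < 0.5 else "-"
    else:  # pragma: no cover
        raise ValidationError(f"unhandled class {cls}")

    width = max(gexons[-1][1], lexons[-1][1]) + 1200  # room for a known-lncRNA extension
    if gene_strand == "-":
        gexons = _mirror(gexons, width)
        lexons = _mirror(lexons, width)
        lnc_strand = _other_strand(lnc_strand)
    return gexons, gene_strand, lexons, lnc_strand, width


EXPECTED_CODE = {
    PositionalClass.INTERGENIC_GT1KB: "u",
    PositionalClass.EXONIC_OVERLAP_SENSE: "o",
    PositionalClass.EXONIC_OVERLAP_ANTISENSE: "x",
    PositionalClass.UPSTREAM_1KB_SENSE: "u",
    PositionalClass.UPSTREAM_1KB_ANTISENSE: "u",
    PositionalClass.DOWNSTREAM_1KB_SENSE: "u",
    PositionalClass.DOWNSTREAM_1KB_ANTISENSE: "u",
    PositionalClass.INTRONIC_SENSE: "i",
    PositionalClass.INTRONIC_ANTISENSE: "i",
    PositionalClass.GENE_IN_LNCRNA_INTRON: "u",
    PositionalClass.BIDIRECTIONAL_PROMOTER_SHARED: "u",
}

INTER_BLOCK_MARGIN = 2500


class _Layout:
    """Round-robin placement of units across chromosomes with margins."""

    def __init__(self, cfg: SimConfig):
        self.chroms = [f"chr{i + 1}" for i in range(cfg.n_chromosomes)]
        self.cursor = {c: 1000 for c in self.chroms}
        self.limit = cfg.chrom_length
        self.i = 0

    def place(self, width: int, feature_name: str) -> tuple[str, int]:
        chrom = self.chroms[self.i % len(self.chroms)]
        self.i += 1
        offset = self.cursor[chrom]
        if offset + width > self.limit:
            raise SizingError(
                f"chromosome {chrom} (length {self.limit}) too short to place {feature_name}"
            )
        self.cursor[chrom] = offset + width + INTER_BLOCK_MARGIN
        return chrom, offset


def generate_annotation(cfg: SimConfig) -> tuple[AnnotationSet, AnnotationSet, TruthTable]:
    """Generate the reference and assembled annotations with planted truth.

    The reference holds protein-coding genes (biotype ``protein_coding``)
    and the known-lncRNA subset (biotype ``lncRNA``); the assembled set
    holds the candidate transcripts.  Identical configurations produce
    byte-identical GTF output.
    """
    cfg.validate()
    ann_ss = np.random.SeedSequence(cfg.seed).spawn(4)[0]
    class_list = _allocate_classes(cfg.class_mix, cfg.n_lncrna)
    n_units = len(class_list) + cfg.n_coding_genes + cfg.n_short_decoys + 3 * cfg.n_code_decoys
    streams = [np.random.default_rng(s) for s in ann_ss.spawn(n_units + 1)]
    known_rng = streams[-1]

    reference = AnnotationSet()
    assembled = AnnotationSet()
    layout = _Layout(cfg)
    feat_rows = []
    gene_rows = []
    tx_rows = []

    known_ids = set(
        known_rng.choice(
            [f"LNC{i:04d}" for i in range(1, cfg.n_lncrna + 1)],
            size=int(round(cfg.known_fraction * cfg.n_lncrna)),
            replace=False,
        )
    )

    cis_by_lnc = {lnc: (gene, r) for lnc, gene, r in cfg.planted_cis}

    # --- lncRNA units ------------------------------------------------------
    for i, cls in enumerate(class_list, 1):
        rng = streams[i - 1]
        lnc_id = f"LNC{i:04d}"
        gene_id = f"G{i:04d}"
        gexons, gstrand, lexons, lstrand, width = _build_unit(cls, rng)
        chrom, off = layout.place(width, lnc_id)
        gexons = [(s + off, e + off) for s, e in gexons]
        lexons = [(s + off, e + off) for s, e in lexons]

        gene_tx = TranscriptModel(f"{gene_id}.T1", chrom, gstrand, tuple(gexons))
        reference.add(gene_tx, gene_id, "protein_coding")
        lnc_tx = TranscriptModel(lnc_id, chrom, lstrand, tuple(lexons))
        assembled.add(lnc_tx, f"XLOC_{i:04d}", "other_ncRNA")

        known = lnc_id in known_ids
        if known:
            nid = f"NONC{i:04d}"
            if rng.random() < 0.5:  # exact copy -> '='
                ref_lnc = TranscriptModel(nid, chrom, lstrand, tuple(lexons))
            else:  # extended chain -> candidate contained, code 'c'
                extra_start = lexons[-1][1] + 400
                ref_lnc = TranscriptModel(
                    nid, chrom, lstrand, tuple(lexons + [(extra_start, extra_start + 300)])
                )
            reference.add(ref_lnc, f"NONCG{i:04d}", "lncRNA")
            tx_rows.append({"transcript_id": nid, "kind": "reference_lncrna",
                            "coding_label": "noncoding", "length": ref_lnc.length})

        partner = cis_by_lnc.get(lnc_id)
        feat_rows.append(
            {
                "feature_id": lnc_id,
                "feature_type": "lncrna_candidate",
                "positional_class": cls.value,
                "expected_code": EXPECTED_CODE[cls],
                "coding_label": "noncoding",
                "known_label": "known" if known else "novel",
                "length": lnc_tx.length,
                "chrom": chrom,
                "host_gene": gene_id,
                "cis_partner": partner[0] if partner else "",
                "cis_r": partner[1] if partner else np.nan,
            }
        )
        gene_rows.append(
            {
                "gene_id": gene_id,
                "chrom": chrom,
                "start": gene_tx.start,
                "end": gene_tx.end,
                "strand": gstrand,
                "length": gene_tx.length,
            }
        )
        tx_rows.append({"transcript_id": lnc_id, "kind": "assembled",
                        "coding_label": "noncoding", "length": lnc_tx.length})
        tx_rows.append({"transcript_id": f"{gene_id}.T1", "kind": "reference_coding",
                        "coding_label": "coding", "length": gene_tx.length})

    # --- standalone coding genes ------------------------------------------
    base = len(class_list)
    standalone: list[TranscriptModel] = []
    for i in range(1, cfg.n_coding_genes + 1):
        rng = streams[base + i - 1]
        gene_id = f"GS{i:04d}"
        gexons = _gene_exons(rng, n_exons=int(rng.integers(3, 11)))
        gstrand = "+" if rng.random() < 0.5 else "-"
        width = gexons[-1][1] + 200
        chrom, off = layout.place(width, gene_id)
        gexons = [(s + off, e + off) for s, e in gexons]
        tx = TranscriptModel(f"{gene_id}.T1", chrom, gstrand, tuple(gexons))
        reference.add(tx, gene_id, "protein_coding")
        standalone.append(tx)
        gene_rows.append({"gene_id": gene_id, "chrom": chrom, "start": tx.start,
                          "end": tx.end, "strand": gstrand, "length": tx.length})
        tx_rows.append({"transcript_id": f"{gene_id}.T1", "kind": "reference_coding",
                        "coding_label": "coding", "length": tx.length})

    # --- short decoys (<200 nt, removed by the length filter) --------------
    base += cfg.n_coding_genes
    for i in range(1, cfg.n_short_decoys + 1):
        rng = streams[base + i - 1]
        sid = f"SHORT{i:03d}"
        length = int(rng.integers(120, 200))
        chrom, off = layout.place(length + 100, sid)
        tx = TranscriptModel(sid, chrom, "+" if rng.random() < 0.5 else "-",
                             ((off, off + length),))
        assembled.add(tx, f"XLOC_S{i:03d}", "other_ncRNA")
        feat_rows.append({"feature_id": sid, "feature_type": "short_decoy",
                          "positional_class": "", "expected_code": "",
                          "coding_label": "noncoding", "known_label": "",
                          "length": length, "chrom": chrom, "host_gene": "",
                          "cis_partner": "", "cis_r": np.nan})
        tx_rows.append({"transcript_id": sid, "kind": "assembled",
                        "coding_label": "noncoding", "length": length})

    # --- coding-overlap decoys (codes =, c, j vs protein-coding genes) -----
    base += cfg.n_short_decoys
    decoy_specs = [("DCOPY", "="), ("DCONT", "c"), ("DISO", "j")]
    for d, (prefix, code) in enumerate(decoy_specs):
        for i in range(1, cfg.n_code_decoys + 1):
            rng = streams[base + d * cfg.n_code_decoys + i - 1]
            did = f"{prefix}{i:03d}"
            host = standalone[d * cfg.n_code_decoys + i - 1]
            if code == "=":
                exons = host.exons
            elif code == "c":
                # two-exon sub-chain of the host with trimmed terminal exons:
                # contained with matching internal splice sites, >=200 nt
                (s1, e1), (s2, e2) = host.exons[0], host.exons[1]
                exons = ((s1 + 5, e1), (s2, e2 - 5))
            else:  # 'j': share intron 1, then diverge inside intron 2
                e1, e2 = host.exons[0], host.exons[1]
                exons = (e1, (e2[0], e2[1] + 50))
            tx = TranscriptModel(did, host.chrom, host.strand, exons)
            assembled.add(tx, f"XLOC_{prefix}{i:03d}", "other_ncRNA")
            feat_rows.append({"feature_id": did, "feature_type": "code_decoy",
                              "positional_class": "", "expected_code": code,
                              "coding_label": "coding", "known_label": "",
                              "length": tx.length, "chrom": tx.chrom,
                              "host_gene": reference.gene_of[host.id],
                              "cis_partner": "", "cis_r": np.nan})
            tx_rows.append({"transcript_id": did, "kind": "assembled",
                            "coding_label": "coding", "length": tx.length})

    features = pd.DataFrame(feat_rows).set_index("feature_id")
    genes = pd.DataFrame(gene_rows).set_index("gene_id")
    transcripts = pd.DataFrame(tx_rows).set_index("transcript_id")
    if features.index.has_duplicates or genes.index.has_duplicates or transcripts.index.has_duplicates:
        raise ValidationError("duplicate feature ids in truth table")

    planted_lfc = pd.DataFrame(
        [
            {"feature_id": fid, "treatment": t, "dayA": a, "dayB": b, "log2fc": lfc}
            for fid, (t, a, b), lfc in cfg.planted_lfc
        ],
        columns=["feature_id", "treatment", "dayA", "dayB", "log2fc"],
    )
    planted_cis = pd.DataFrame(
        [{"lncrna_id": l, "gene_id": g, "target_r": r} for l, g, r in cfg.planted_cis],
        columns=["lncrna_id", "gene_id", "target_r"],
    )

    # cis pairs must exist and sit within the 50 kb window
    for _, row in planted_cis.iterrows():
        lnc, gid = row["lncrna_id"], row["gene_id"]
        if lnc not in features.index or gid not in genes.index:
            raise ValidationError(f"planted cis pair ({lnc}, {gid}): unknown feature")
        lnc_tx = assembled.transcripts[lnc]
        gs, ge = genes.loc[gid, "start"], genes.loc[gid, "end"]
        gap = max(lnc_tx.start - ge, gs - lnc_tx.end, 0)
        if genes.loc[gid, "chrom"] != lnc_tx.chrom or gap > 50_000:
            raise ValidationError(f"planted cis pair ({lnc}, {gid}) not within 50 kb")

    truth = TruthTable(features, genes, transcripts, planted_lfc, planted_cis)
    return reference, assembled, truth


# ---------------------------------------------------------------------------
# Sequence generator
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT" if a + b + c not in _STOPS]
# fixed codon-usage bias for coding sequences (deterministic, seed-independent)
_CODON_WEIGHTS = np.random.default_rng(201811).dirichlet(np.full(len(_SENSE_CODONS), 0.35))


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _coding_seq(rng: np.random.Generator, length: int) -> str:
    """Sequence with an in-frame ORF covering >=55% of the transcript."""
    orf_nt = 3 * int(math.ceil(0.55 * length / 3)) + 6
    orf_nt = min(orf_nt, length - (length % 3))
    n_codons = orf_nt // 3 - 2  # minus start and stop
    codons = rng.choice(_SENSE_CODONS, size=n_codons, p=_CODON_WEIGHTS)
    orf = "ATG" + "".join(codons) + "TAA"
    utr5 = (length - len(orf)) // 2
    utr3 = length - len(orf) - utr5
    return _random_seq(rng, utr5) + orf + _random_seq(rng, utr3)


def generate_sequences(cfg: SimConfig, truth: TruthTable) -> dict[str, str]:
    """Transcript sequences consistent with the truth table's lengths.

    Coding-labeled transcripts carry a long in-frame codon-biased ORF;
    non-coding transcripts are uniform random.  Deterministic per seed.
    """
    cfg.validate()
    if truth.transcripts.empty:
        raise ValidationError("truth table has no transcripts")
    seq_ss = np.random.SeedSequence(cfg.seed).spawn(4)[1]
    streams = seq_ss.spawn(len(truth.transcripts))
    seqs: dict[str, str] = {}
    for (tid, row), ss in zip(truth.transcripts.sort_index().iterrows(), streams):
        rng = np.random.default_rng(ss)
        length = int(row["length"])
        if row["coding_label"] == "coding":
            seqs[tid] = _coding_seq(rng, length)
        else:
            seqs[tid] = _random_seq(rng, length)
    return seqs


# ---------------------------------------------------------------------------
# Count generator
# ---------------------------------------------------------------------------


def _library_table(design: Design) -> pd.DataFrame:
    rows = []
    for t in design.treatments:
        for cow in range(1, design.cows_per_treatment + 1):
            for day in design.days:
                rows.append(
                    {
                        "library_id": f"{t}_cow{cow:02d}_{day}",
                        "cow": f"{t}_cow{cow:02d}",
                        "treatment": t,
                        "day": day,
                    }
                )
    return pd.DataFrame(rows).set_index("library_id")


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    n = 1.0 / dispersion
    p = n / (n + mu)
    return rng.negative_binomial(n, p)


def _calibrate_latent_scale(
    target_r: float,
    mu_a: float,
    mu_b: float,
    dispersion: float,
    n: int,
    rng: np.random.Generator,
    reps: int = 150,
) -> float:
    """1-D search for the shared log2-scale latent weight matching target r.

    Simulates the realized Pearson correlation of log2(count + 1) between
    the two pair members at sample size ``n`` and bisects on the latent
    weight; the mean realized correlation is matched to the target.
    """

    def realized(s: float) -> float:
        z = rng.normal(size=(reps, n))
        corr = 2.0 ** (s * z) / np.exp(0.5 * (s * np.log(2.0)) ** 2)
        ka = np.log2(_nb_draw(rng, mu_a * corr, dispersion) + 1.0)
        kb = np.log2(_nb_draw(rng, mu_b * corr, dispersion) + 1.0)
        ka_c = ka - ka.mean(axis=1, keepdims=True)
        kb_c = kb - kb.mean(axis=1, keepdims=True)
        denom = np.sqrt((ka_c**2).sum(axis=1) * (kb_c**2).sum(axis=1))
        ok = denom > 0
        return float(((ka_c * kb_c).sum(axis=1)[ok] / denom[ok]).mean())

    lo, hi = 0.01, 4.0
    for _ in range(18):
        mid = 0.5 * (lo + hi)
        if realized(mid) < target_r:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_counts(cfg: SimConfig, truth: TruthTable):
    """NB fragment counts for all assembled candidates and coding genes.

    Returns (CountMatrix, LibraryDesign DataFrame).  Counts follow
    NB(mu, dispersion) with per-feature base means drawn lognormal and
    scaled to the configured library depth; planted log2FCs scale the
    affected (treatment, day) cells, and planted cis pairs share a latent
    lognormal factor calibrated to the target correlation.
    """
    from .expression import CountMatrix  # local import to avoid a cycle

    cfg.validate()
    count_ss = np.random.SeedSequence(cfg.seed).spawn(4)[2]
    base_ss, latent_ss, noise_ss, calib_ss = count_ss.spawn(4)
    design = _library_table(cfg.design)

    feature_ids = list(truth.features.index) + list(truth.genes.index)
    lengths = pd.concat(
        [truth.features["length"], truth.genes["length"]]
    ).reindex(feature_ids)

    base_rng = np.random.default_rng(base_ss)
    raw_means = np.exp(base_rng.normal(np.log(1.0), 1.0, size=len(feature_ids)))
    base_means = pd.Series(
        raw_means * cfg.mean_depth / raw_means.sum(), index=feature_ids
    )

    # expression multipliers from planted log2FCs
    mult = pd.DataFrame(1.0, index=feature_ids, columns=design.index)
    for _, row in truth.planted_lfc.iterrows():
        libs = design.index[
            (design["treatment"] == row["treatment"]) & (design["day"] == row["dayB"])
        ]
        if row["feature_id"] in mult.index:
            mult.loc[row["feature_id"], libs] *= 2.0 ** row["log2fc"]

    # shared latent factors for planted cis pairs; one stream per pair so
    # adding pairs does not perturb earlier draws
    latent = pd.DataFrame(0.0, index=feature_ids, columns=design.index)
    scale = pd.Series(0.0, index=feature_ids)
    n_pairs = max(len(truth.planted_cis), 1)
    latent_streams = latent_ss.spawn(n_pairs)
    calib_streams = calib_ss.spawn(n_pairs)
    for (_, row), lss, css in zip(truth.planted_cis.iterrows(), latent_streams, calib_streams):
        lnc, gid, r = row["lncrna_id"], row["gene_id"], row["target_r"]
        s = _calibrate_latent_scale(
            float(r),
            float(base_means[lnc]),
            float(base_means[gid]),
            cfg.nb_dispersion,
            n=len(cfg.design.days) * cfg.design.cows_per_treatment,
            rng=np.random.default_rng(css),
        )
        z = np.random.default_rng(lss).normal(size=len(design.index))
        for fid in (lnc, gid):
            latent.loc[fid] = z
            scale[fid] = s

    corr = 2.0 ** (scale.values[:, None] * latent.values) / np.exp(
        0.5 * (scale.values[:, None] * np.log(2.0)) ** 2
    )
    mu = base_means.values[:, None] * mult.values * corr
    noise_streams = noise_ss.spawn(len(feature_ids))
    counts = np.vstack(
        [
            _nb_draw(np.random.default_rng(ss), mu[i], cfg.nb_dispersion)
            for i, ss in enumerate(noise_streams)
        ]
    )
    cm = CountMatrix(
        pd.DataFrame(counts, index=feature_ids, columns=design.index), lengths
    )
    return cm, design


def generate_term_table(cfg: SimConfig, truth: TruthTable, n_terms: int = 24) -> pd.DataFrame:
    """A synthetic gene->term map over the coding genes, for enrichment runs."""
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(4)[3])
    genes = list(truth.genes.index)
    sources = ["GO_BP"] * (n_terms // 2) + ["GO_CC"] * (n_terms // 6) + ["GO_MF"] * (n_terms // 6)
    sources += ["PATHWAY"] * (n_terms - len(sources))
    rows = []
    for i, source in enumerate(sources, 1):
        size = int(rng.integers(5, max(6, len(genes) // 4)))
        members = rng.choice(genes, size=min(size, len(genes)), replace=False)
        tid = f"TERM:{i:04d}"
        for g in sorted(members):
            rows.append({"gene_id": g, "term_id": tid, "term_name": f"synthetic term {i}", "source": source})
    return pd.DataFrame(rows, columns=["gene_id", "term_id", "term_name", "source"])
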