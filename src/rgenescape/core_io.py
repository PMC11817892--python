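"""Readers and writers for the formats every pipeline stage touches.

All coordinates are converted to 0-based half-open intervals at the
boundary of this module: GFF3 and VCF are 1-based inclusive on disk and
nowhere else.  Downstream modules never see 1-based coordinates.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

NUCLEOTIDES = set("ACGTN")

#: the five domain labels the R-gene classifier understands
DOMAIN_VOCABULARY = ("TIR", "CC", "NB-ARC", "LRR", "RPW8")

#: structural-variant types consumed from VCF
SV_TYPES = ("DEL", "INS", "INV")

TE_CLASSES = ("LTR/Gypsy", "LTR/Copia", "TIR/Mutator", "LINE", "Helitron", "other")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class GenomeSequence:
    chrom_id: str
    seq: str

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass
class GeneModel:
    """A stranded gene with coding sub-intervals, half-open coordinates."""

    gene_id: str
    chrom_id: str
    start: int
    end: int
    strand: str
    coding_intervals: list[tuple[int, int]] = field(default_factory=list)
    protein_seq: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"gene {self.gene_id}: start must be < end")
        if self.strand not in {"+", "-"}:
            raise FormatError(f"gene {self.gene_id}: strand must be '+' or '-'")
        self.coding_intervals = merge_intervals(self.coding_intervals)
        for s, e in self.coding_intervals:
            if s < self.start or e > self.end:
                raise ValueError(
                    f"gene {self.gene_id}: CDS [{s},{e}) outside gene span"
                )

    @property
    def coding_length(self) -> int:
        return sum(e - s for s, e in self.coding_intervals)


@dataclass
class TEFeature:
    chrom_id: str
    start: int
    end: int
    te_class: str
    intact: bool = False

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("TE interval must have start < end")
        if self.te_class not in TE_CLASSES:
            raise ValueError(f"unknown TE class {self.te_class!r}")


@dataclass
class IntactLTR:
    te: TEFeature
    ltr5_seq: str
    ltr3_seq: str

    def __post_init__(self) -> None:
        if not self.ltr5_seq or not self.ltr3_seq:
            raise ValueError("both LTR sequences must be non-empty")


@dataclass
class SVRecord:
    sv_id: str
    chrom_id: str
    pos: int  # 0-based
    sv_type: str
    length: int
    source_haplotype: str

    def __post_init__(self) -> None:
        if self.sv_type not in SV_TYPES:
            raise ValueError(f"unknown SV type {self.sv_type!r}")
        if self.length <= 0:
            raise ValueError("SV length must be positive")

    @property
    def span(self) -> tuple[int, int]:
        """Reference footprint; insertions occupy a single-bp point interval."""
        if self.sv_type == "INS":
            return (self.pos, self.pos + 1)
        return (self.pos, self.pos + self.length)


@dataclass
class DomainHit:
    gene_id: str
    domain: str
    evalue: float
    qstart: int
    qend: int

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("e-value must be >= 0")
        if self.domain not in DOMAIN_VOCABULARY:
            raise ValueError(f"unknown domain label {self.domain!r}")


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Sort and union half-open intervals; abutting intervals are joined."""
    ivs = sorted((int(s), int(e)) for s, e in intervals)
    out: list[tuple[int, int]] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def union_length(intervals: Iterable[tuple[int, int]]) -> int:
    return sum(e - s for s, e in merge_intervals(intervals))


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path, alphabet: Optional[set] = NUCLEOTIDES) -> list[GenomeSequence]:
    """Read a FASTA file into uppercased records; duplicate ids are fatal.

    Pass ``alphabet=None`` to skip residue validation (e.g. protein FASTA).
    """
    path = Path(path)
    records = []
    seen: dict[str, int] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if rec.id in seen:
            line_no = _header_line(path, rec.id, occurrence=2)
            raise FormatError(
                f"{path}: duplicate sequence id {rec.id!r} (line {line_no})"
            )
        if alphabet is not None:
            bad = set(seq) - alphabet
            if bad:
                raise FormatError(
                    f"{path}: record {rec.id!r} contains non-nucleotide "
                    f"characters {sorted(bad)}"
                )
        seen[rec.id] = 1
        records.append(GenomeSequence(rec.id, seq))
    return records


def read_protein_fasta(path: str | Path) -> dict[str, str]:
    return {r.chrom_id: r.seq for r in read_fasta(path, alphabet=None)}


def _header_line(path: Path, rec_id: str, occurrence: int = 1) -> int:
    n = 0
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            if line.startswith(">") and line[1:].split()[0] == rec_id:
                n += 1
                if n == occurrence:
                    return i
    return -1


def write_fasta(records: Iterable[GenomeSequence], path: str | Path) -> None:
    seqs = [SeqRecord(Seq(r.seq), id=r.chrom_id, description="") for r in records]
    SeqIO.write(seqs, str(path), "fasta")


def write_protein_fasta(proteins: dict[str, str], path: str | Path) -> None:
    seqs = [SeqRecord(Seq(s), id=gid, description="") for gid, s in proteins.items()]
    SeqIO.write(seqs, str(path), "fasta")


# ---------------------------------------------------------------------------
# GFF3 gene models


def read_gff_genes(path: str | Path) -> list[GeneModel]:
    """Parse gene/mRNA/CDS features from GFF3 into half-open GeneModels.

    Coding intervals are the per-gene union of CDS across all isoforms.
    CDS features whose Parent chain does not reach a gene are fatal.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    gene_ids = {f.id for f in db.features_of_type("gene")}
    mrna_parent: dict[str, str] = {}
    for mrna in db.features_of_type("mRNA"):
        parents = mrna.attributes.get("Parent", [])
        if parents:
            mrna_parent[mrna.id] = parents[0]

    cds_by_gene: dict[str, list[tuple[int, int]]] = {}
    orphans: list[str] = []
    for cds in db.features_of_type("CDS"):
        gene = None
        for p in cds.attributes.get("Parent", []):
            if p in gene_ids:
                gene = p
            elif p in mrna_parent and mrna_parent[p] in gene_ids:
                gene = mrna_parent[p]
        if gene is None:
            orphans.append(cds.id or str(cds.attributes.get("Parent", ["?"])[0]))
            continue
        # GFF is 1-based inclusive -> half-open
        cds_by_gene.setdefault(gene, []).append((cds.start - 1, cds.end))
    if orphans:
        raise FormatError(f"{path}: CDS features with no parent gene: {sorted(set(orphans))}")

    genes = []
    for f in db.features_of_type("gene"):
        if f.strand not in {"+", "-"}:
            raise FormatError(f"{path}: gene {f.id}: strand {f.strand!r} not oriented")
        genes.append(
            GeneModel(
                gene_id=f.id,
                chrom_id=f.seqid,
                start=f.start - 1,
                end=f.end,
                strand=f.strand,
                coding_intervals=cds_by_gene.get(f.id, []),
            )
        )
    genes.sort(key=lambda g: (g.chrom_id, g.start))
    return genes


def write_gff_genes(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom_id}\trgenescape\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )
            mrna = f"{g.gene_id}.t1"
            fh.write(
                f"{g.chrom_id}\trgenescape\tmRNA\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={mrna};Parent={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.coding_intervals, 1):
                fh.write(
                    f"{g.chrom_id}\trgenescape\tCDS\t{s + 1}\t{e}\t.\t"
                    f"{g.strand}\t0\tID={mrna}.cds{i};Parent={mrna}\n"
                )


# ---------------------------------------------------------------------------
# TE annotations (GFF3 with class/intact attributes)


def read_te_gff(path: str | Path) -> list[TEFeature]:
    tes = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9:
                raise FormatError(f"{path}: TE line with <9 columns: {line!r}")
            attrs = dict(
                kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv
            )
            te_class = attrs.get("te_class", "other")
            if te_class not in TE_CLASSES:
                te_class = "other"
            tes.append(
                TEFeature(
                    chrom_id=cols[0],
                    start=int(cols[3]) - 1,
                    end=int(cols[4]),
                    te_class=te_class,
                    intact=attrs.get("intact", "0") == "1",
                )
            )
    return tes


def write_te_gff(tes: Iterable[TEFeature], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, te in enumerate(tes):
            fh.write(
                f"{te.chrom_id}\trgenescape\ttransposable_element\t{te.start + 1}\t"
                f"{te.end}\t.\t+\t.\tID=te{i};te_class={te.te_class};"
                f"intact={int(te.intact)}\n"
            )


def read_intact_ltrs(path: str | Path) -> list[IntactLTR]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples(index=False):
        te = TEFeature(row.chrom_id, int(row.start), int(row.end), row.te_class, True)
        out.append(IntactLTR(te, row.ltr5_seq, row.ltr3_seq))
    return out


def write_intact_ltrs(ltrs: Iterable[IntactLTR], path: str | Path) -> None:
    rows = [
        {
            "chrom_id": l.te.chrom_id,
            "start": l.te.start,
            "end": l.te.end,
            "te_class": l.te.te_class,
            "ltr5_seq": l.ltr5_seq,
            "ltr3_seq": l.ltr3_seq,
        }
        for l in ltrs
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# SV VCF


@dataclass
class SVReadResult:
    records: list[SVRecord]
    skipped: Counter  # SVTYPE -> count of skipped records
    errors: list[str]  # record-level problems (file still processed)


def read_sv_vcf(path: str | Path, source_haplotype: str) -> SVReadResult:
    """Read DEL/INS/INV records from an SV VCF.

    Other SVTYPEs are skipped and tallied; records missing SVTYPE are
    reported per-record without aborting the file.
    """
    from cyvcf2 import VCF

    records: list[SVRecord] = []
    skipped: Counter = Counter()
    errors: list[str] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        vcf = VCF(str(path))
        for i, v in enumerate(vcf):
            svtype = v.INFO.get("SVTYPE")
            if svtype is None:
                errors.append(f"record {i + 1} ({v.CHROM}:{v.POS}): missing SVTYPE")
                continue
            if svtype not in SV_TYPES:
                skipped[svtype] += 1
                continue
            svlen = v.INFO.get("SVLEN")
            if isinstance(svlen, (tuple, list)):
                svlen = svlen[0]
            if svlen is not None:
                length = abs(int(svlen))
            else:
                end = v.INFO.get("END")
                length = int(end) - v.POS if end is not None else None
            if not length:
                errors.append(f"record {i + 1} ({v.CHROM}:{v.POS}): no usable length")
                continue
            records.append(
                SVRecord(
                    sv_id=v.ID or f"{source_haplotype}_sv{i + 1}",
                    chrom_id=v.CHROM,
                    pos=v.POS - 1,
                    sv_type=svtype,
                    length=length,
                    source_haplotype=source_haplotype,
                )
            )
        vcf.close()
    return SVReadResult(records, skipped, errors)


def write_sv_vcf(
    records: Iterable[SVRecord],
    path: str | Path,
    contigs: dict[str, int],
    extra_info: Optional[dict[str, dict[str, str]]] = None,
) -> None:
    """Write a minimal SV VCF (SVTYPE/SVLEN/END in INFO).

    ``extra_info`` maps sv_id -> additional INFO key/value pairs.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, length in contigs.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n')
        fh.write('##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">\n')
        fh.write('##INFO=<ID=END,Number=1,Type=Integer,Description="SV end">\n')
        fh.write('##INFO=<ID=ZYG,Number=1,Type=String,Description="Zygosity">\n')
        fh.write('##INFO=<ID=SUPP,Number=1,Type=String,Description="Supporting haplotypes">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for r in sorted(records, key=lambda x: (x.chrom_id, x.pos)):
            svlen = -r.length if r.sv_type == "DEL" else r.length
            end = r.pos + (r.length if r.sv_type != "INS" else 0)
            info = f"SVTYPE={r.sv_type};SVLEN={svlen};END={end + 1}"
            if extra_info and r.sv_id in extra_info:
                info += "".join(f";{k}={v}" for k, v in extra_info[r.sv_id].items())
            fh.write(
                f"{r.chrom_id}\t{r.pos + 1}\t{r.sv_id}\tN\t<{r.sv_type}>\t.\tPASS\t{info}\n"
            )


# ---------------------------------------------------------------------------
# Tabular inputs


@dataclass
class DomainHitResult:
    hits: list[DomainHit]
    ignored_labels: Counter  # unrecognized domain label -> count


def read_domain_hits(path: str | Path) -> DomainHitResult:
    """Read a domain-hit TSV (gene_id, domain, evalue, qstart, qend).

    Labels outside the closed vocabulary are ignored and tallied.
    """
    df = pd.read_csv(path, sep="\t")
    hits: list[DomainHit] = []
    ignored: Counter = Counter()
    for row in df.itertuples(index=False):
        if row.domain not in DOMAIN_VOCABULARY:
            ignored[row.domain] += 1
            continue
        hits.append(
            DomainHit(row.gene_id, row.domain, float(row.evalue), int(row.qstart), int(row.qend))
        )
    if ignored:
        warnings.warn(
            f"{path}: ignored {sum(ignored.values())} hits with labels outside "
            f"the domain vocabulary: {dict(ignored)}"
        )
    return DomainHitResult(hits, ignored)


def write_domain_hits(hits: Iterable[DomainHit], path: str | Path) -> None:
    rows = [
        {"gene_id": h.gene_id, "domain": h.domain, "evalue": h.evalue,
         "qstart": h.qstart, "qend": h.qend}
        for h in hits
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_allele_counts(path: str | Path) -> pd.DataFrame:
    """Read allele counts at heterozygous SNPs (gene_id snp_id hap1 hap2)."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "snp_id", "hap1", "hap2"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: allele-count table missing columns {sorted(missing)}")
    if (df[["hap1", "hap2"]] < 0).any().any():
        raise FormatError(f"{path}: negative allele counts")
    return df


def write_allele_counts(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
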