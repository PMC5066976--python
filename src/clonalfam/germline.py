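"""Germline V/D/J gene sets and conserved CDR3 anchors.

The state space of the rearrangement HMM is defined by a set of germline
genes: every position of every retained V, D and J allele becomes a hidden
state.  Alongside the sequences we require the positions of the conserved
CDR3 anchor codons -- the cysteine near the 3' end of each V gene and the
tryptophan in each J gene -- because every downstream stage (CDR3 bounds,
cysteine-aligned naive-sequence comparison, indel placement) is expressed
relative to those codons.

Coordinates are 0-based and intervals are half-open throughout.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = frozenset("ACGT")
REGIONS = ("V", "D", "J")

_ANCHOR_TAG = re.compile(r"\|anchor=(\d+)\s*$")


class GermlineError(ValueError):
    """Invalid germline input (bad alphabet, missing anchors, ...)."""


class AnchorEroded(ValueError):
    """A rearrangement's deletions removed a conserved anchor codon."""


@dataclass(frozen=True)
class GermlineGene:
    """One germline allele.

    Parameters
    ----------
    name : str
        Gene/allele identifier, unique within a set.
    region : {"V", "D", "J"}
    seq : str
        Nucleotide sequence over {A, C, G, T}.
    anchor : int or None
        0-based start of the conserved codon (cysteine for V, tryptophan
        for J); ``None`` for D genes, which carry no anchor.
    """

    name: str
    region: str
    seq: str
    anchor: int | None = None

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise GermlineError(f"unknown region {self.region!r} for {self.name}")
        if not self.seq:
            raise GermlineError(f"empty sequence for {self.name}")
        bad = set(self.seq) - VALID_BASES
        if bad:
            raise GermlineError(
                f"{self.name}: invalid characters {sorted(bad)} (alphabet is ACGT)"
            )
        if self.anchor is not None and not 0 <= self.anchor <= len(self.seq) - 3:
            raise GermlineError(
                f"{self.name}: anchor {self.anchor} outside [0, {len(self.seq) - 3}]"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class GermlineSet:
    """All germline genes for one locus, grouped by region."""

    genes: dict[str, list[GermlineGene]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names: list[str] = []
        for region in REGIONS:
            region_genes = self.genes.get(region, [])
            if not region_genes:
                raise GermlineError(f"no {region} genes in germline set")
            for g in region_genes:
                if g.region != region:
                    raise GermlineError(f"{g.name} filed under {region} but is {g.region}")
                if region in ("V", "J") and g.anchor is None:
                    raise GermlineError(
                        f"{g.name}: {region} genes require a conserved-codon anchor"
                    )
                names.append(g.name)
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise GermlineError(f"duplicate gene names: {sorted(dupes)}")
        self._by_name = {g.name: g for gs in self.genes.values() for g in gs}

    def __getitem__(self, name: str) -> GermlineGene:
        return self._by_name[name]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __len__(self) -> int:
        return len(self._by_name)

    def region_genes(self, region: str) -> list[GermlineGene]:
        return list(self.genes[region])

    def names(self, region: str | None = None) -> list[str]:
        if region is None:
            return list(self._by_name)
        return [g.name for g in self.genes[region]]

    def to_fasta(self, v_path, d_path, j_path) -> None:
        """Write one FASTA per region, anchors tagged as ``|anchor=N``."""
        for region, path in zip(REGIONS, (v_path, d_path, j_path)):
            records = []
            for g in self.genes[region]:
                header = g.name if g.anchor is None else f"{g.name}|anchor={g.anchor}"
                records.append(SeqRecord(Seq(g.seq), id=header, description=""))
            SeqIO.write(records, path, "fasta")


def _parse_region_fasta(path, region: str, anchors: dict[str, int] | None) -> list[GermlineGene]:
    genes = []
    for rec in SeqIO.parse(str(path), "fasta"):
        header = rec.id
        anchor = None
        m = _ANCHOR_TAG.search(header)
        if m:
            anchor = int(m.group(1))
            header = header[: m.start()]
        if anchors and header in anchors:
            anchor = anchors[header]
        genes.append(GermlineGene(header, region, str(rec.seq).upper(), anchor))
    if not genes:
        raise GermlineError(f"no {region} genes found in {path}")
    return genes


def load_germline_set(v_path, d_path, j_path, anchors=None) -> GermlineSet:
    """Load a germline set from three per-region FASTA files.

    Anchors (conserved cysteine position for V, tryptophan for J; 0-based
    codon start) may be given either as a ``|anchor=N`` suffix on the FASTA
    header or through ``anchors``: a mapping of gene name to position, or a
    path to a two-column CSV ``gene,anchor``.  V and J genes without an
    anchor are rejected, as are sequences with characters outside ACGT.
    """
    anchor_map: dict[str, int] = {}
    if anchors is not None:
        if isinstance(anchors, (str, Path)):
            with open(anchors, newline="") as fh:
                for row in csv.reader(fh):
                    if not row or row[0].strip().lower() in ("gene", ""):
                        continue
                    anchor_map[row[0].strip()] = int(row[1])
        else:
            anchor_map = dict(anchors)
    genes = {
        region: _parse_region_fasta(path, region, anchor_map)
        for region, path in zip(REGIONS, (v_path, d_path, j_path))
    }
    return GermlineSet(genes)


def fixture_germline_set() -> GermlineSet:
    """The synthetic germline set shipped with the package.

    Six V, three D and four J genes of realistic layout but made-up
    sequence (see ``clonalfam/data``); every test and example runs against
    it without downloads.  Real IMGT-style sets load through
    :func:`load_germline_set` in exactly the same way.
    """
    data = resources.files("clonalfam") / "data"
    return load_germline_set(
        data / "v_synthetic.fasta",
        data / "d_synthetic.fasta",
        data / "j_synthetic.fasta",
    )


def cdr3_bounds(annotation, germline: GermlineSet) -> tuple[int, int]:
    """CDR3 interval on an annotation's naive sequence, 0-based half-open.

    Runs from the start of the V conserved cysteine codon through the end
    of the J tryptophan codon.  Raises :class:`AnchorEroded` when the
    annotation's exonuclease deletions removed either anchor codon.
    """
    v_gene = germline[annotation.v_gene]
    j_gene = germline[annotation.j_gene]
    v_3p, d_5p, d_3p, j_5p = annotation.erosions
    v_len = len(v_gene) - v_3p
    if v_gene.anchor + 3 > v_len:
        raise AnchorEroded(
            f"V 3' deletion of {v_3p} erodes the cysteine of {v_gene.name}"
        )
    if j_5p > j_gene.anchor:
        raise AnchorEroded(
            f"J 5' deletion of {j_5p} erodes the tryptophan of {j_gene.name}"
        )
    d_len = len(germline[annotation.d_gene]) - d_5p - d_3p
    j_offset = v_len + len(annotation.vd_insertion) + d_len + len(annotation.dj_insertion)
    start = v_gene.anchor
    end = j_offset + (j_gene.anchor - j_5p) + 3
    if not 0 <= start < end:
        raise AnchorEroded(f"degenerate CDR3 interval ({start}, {end})")
    return start, end
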