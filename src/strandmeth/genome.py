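"""Reference-region model and in-silico bisulfite conversion.

A CpG dinucleotide is palindromic: the sense strand carries the C at
position p and the antisense strand carries its partner C opposite the G
at p+1.  Sites are numbered 1..N in the sense-strand 5'->3' order and the
same numbering is used when the antisense strand is analyzed, so both
strands of one site always share an index.

Bisulfite conversion deaminates every unmethylated cytosine to uracil
(read as T) and leaves 5-methylcytosine intact; it acts independently on
each strand.  Conversion of the antisense strand is modeled as conversion
of the reverse complement, with calls re-indexed back to sense-strand
site numbers.

Long poly-T homopolymers that appear after conversion defeat Sanger
sequencing; every site read after the start of such a run is flagged
unreadable (in the region modeled here a 16-bp poly-T on the converted
antisense strand truncates reads after site 20).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

SENSE = "sense"
ANTISENSE = "antisense"
STRANDS = (SENSE, ANTISENSE)

_VALID_BASES = frozenset("ACGTN")


@dataclass(frozen=True)
class ReferenceRegion:
    """A contiguous stretch of a source record, 1-based inclusive coordinates."""

    accession_id: str
    sequence: str
    start_coord: int = 1
    end_coord: int = 0
    description: str = ""

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if not seq:
            raise ValueError("reference sequence is empty")
        bad = set(seq) - _VALID_BASES
        if bad:
            raise ValueError(f"invalid bases in reference sequence: {sorted(bad)}")
        if self.end_coord == 0:
            object.__setattr__(self, "end_coord", self.start_coord + len(seq) - 1)
        if self.end_coord - self.start_coord + 1 != len(seq):
            raise ValueError("end_coord - start_coord + 1 must equal sequence length")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def reverse_complement(self) -> str:
        return str(Seq(self.sequence).reverse_complement())

    @classmethod
    def from_fasta(cls, path) -> "ReferenceRegion":
        """Read a single-record FASTA.

        A description line formatted ``accession:start-end`` is parsed into
        the source coordinates; otherwise the record id is the accession and
        the region starts at 1.
        """
        records = list(SeqIO.parse(str(path), "fasta"))
        if len(records) != 1:
            raise ValueError(f"expected exactly one FASTA record, found {len(records)}")
        rec = records[0]
        m = re.match(r"^(?P<acc>[^\s:]+):(?P<start>\d+)-(?P<end>\d+)$", rec.id)
        if m:
            return cls(
                accession_id=m.group("acc"),
                sequence=str(rec.seq),
                start_coord=int(m.group("start")),
                end_coord=int(m.group("end")),
                description=rec.description,
            )
        return cls(
            accession_id=rec.id,
            sequence=str(rec.seq),
            start_coord=1,
            description=rec.description,
        )

    def to_fasta(self, path) -> None:
        header = f"{self.accession_id}:{self.start_coord}-{self.end_coord}"
        with open(path, "w") as fh:
            fh.write(f">{header} {self.description}\n".rstrip() + "\n")
            for i in range(0, len(self.sequence), 70):
                fh.write(self.sequence[i : i + 70] + "\n")


class CpGSite(NamedTuple):
    index: int
    sense_c_pos: int       # 1-based position of the C on the sense strand
    antisense_c_pos: int   # 1-based sense coordinate of the G; its antisense partner is the C


@dataclass(frozen=True)
class CpGSiteMap:
    """Ordered, numbered CpG sites with paired sense/antisense coordinates."""

    sites: tuple[CpGSite, ...]

    def __post_init__(self) -> None:
        for k, site in enumerate(self.sites, start=1):
            if site.index != k:
                raise ValueError("site indices must be 1..N consecutive")
            if site.antisense_c_pos != site.sense_c_pos + 1:
                raise ValueError("antisense partner must sit at sense_c_pos + 1")

    def __len__(self) -> int:
        return len(self.sites)

    def __iter__(self):
        return iter(self.sites)

    @property
    def indices(self) -> tuple[int, ...]:
        return tuple(s.index for s in self.sites)

    def site(self, index: int) -> CpGSite:
        return self.sites[index - 1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.sites, columns=["index", "sense_c_pos", "antisense_c_pos"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "CpGSiteMap":
        df = pd.read_csv(path, sep="\t")
        return cls(tuple(CpGSite(int(r["index"]), int(r["sense_c_pos"]), int(r["antisense_c_pos"]))
                         for _, r in df.iterrows()))


def enumerate_cpg_sites(region: ReferenceRegion, window_start: int = 1,
                        window_end: int | None = None) -> CpGSiteMap:
    """Number every CG dinucleotide inside the window 1..N, 5'->3' on sense.

    Positions are 1-based relative to the region sequence.  Dinucleotides
    containing N are skipped with a logged warning.
    """
    seq = region.sequence
    if window_end is None:
        window_end = len(seq)
    if not (1 <= window_start <= window_end <= len(seq)):
        raise ValueError(f"window [{window_start}, {window_end}] outside region of length {len(seq)}")
    if "N" in seq[window_start - 1 : window_end]:
        logger.warning("N bases inside window; any CpG overlapping an N is skipped")
    sites = []
    for p in range(window_start, window_end):  # p is 1-based; dinucleotide p..p+1
        if seq[p - 1] == "C" and seq[p] == "G":
            sites.append(CpGSite(len(sites) + 1, p, p + 1))
    return CpGSiteMap(tuple(sites))


@dataclass(frozen=True)
class MethylationState:
    """Per-site methylation, either molecule-level flags or population fractions.

    ``values`` maps site index -> flag (0/1) or fraction in [0, 1].  How the
    two strands share the assignment is controlled by ``strand_mode``:
    symmetric (both strands), sense_only, antisense_only, or independent
    (``antisense_values`` then supplies the antisense assignment).
    """

    values: Mapping[int, float]
    strand_mode: str = "symmetric"
    antisense_values: Mapping[int, float] | None = None

    _MODES = ("symmetric", "sense_only", "antisense_only", "independent")

    def __post_init__(self) -> None:
        if self.strand_mode not in self._MODES:
            raise ValueError(f"unknown strand_mode {self.strand_mode!r}")
        if self.strand_mode == "independent" and self.antisense_values is None:
            raise ValueError("independent strand_mode requires antisense_values")
        for vals in (self.values, self.antisense_values or {}):
            for i, v in vals.items():
                if not 0.0 <= float(v) <= 1.0:
                    raise ValueError(f"fraction for site {i} outside [0, 1]: {v}")

    def strand_values(self, strand: str) -> dict[int, float]:
        if strand not in STRANDS:
            raise ValueError(f"unknown strand {strand!r}")
        zero = {i: 0.0 for i in self.values}
        if self.strand_mode == "symmetric":
            return dict(self.values)
        if self.strand_mode == "sense_only":
            return dict(self.values) if strand == SENSE else zero
        if self.strand_mode == "antisense_only":
            return dict(self.values) if strand == ANTISENSE else zero
        return dict(self.values) if strand == SENSE else dict(self.antisense_values)

    def is_molecule(self) -> bool:
        vals = list(self.values.values()) + list((self.antisense_values or {}).values())
        return all(float(v) in (0.0, 1.0) for v in vals)

    def validate_sites(self, site_map: CpGSiteMap) -> None:
        valid = set(site_map.indices)
        for vals in (self.values, self.antisense_values or {}):
            extra = set(vals) - valid
            if extra:
                raise ValueError(f"state references unknown site indices: {sorted(extra)}")


@dataclass(frozen=True)
class BisulfiteTemplate:
    """One strand after bisulfite conversion, written template 5'->3'."""

    strand: str
    converted_sequence: str
    source_state: MethylationState
    unreadable_site_indices: frozenset[int] = field(default_factory=frozenset)


def bisulfite_convert(region: ReferenceRegion, strand: str, state: MethylationState,
                      site_map: CpGSiteMap, min_run_length: int = 16) -> BisulfiteTemplate:
    """Convert one strand of a single molecule.

    Every C that is not a methylated CpG cytosine of that strand becomes T;
    methylated CpG cytosines are retained; other bases (including N) pass
    through unchanged.  Population (fractional) states are rejected: a
    molecule either is or is not methylated at a site.
    """
    if strand not in STRANDS:
        raise ValueError(f"unknown strand {strand!r}")
    state.validate_sites(site_map)
    if not state.is_molecule():
        raise ValueError("molecule-level conversion requires binary methylation flags; "
                         "population fractions are handled by the synthetic-data generator")
    vals = state.strand_values(strand)
    length = len(region)
    if strand == SENSE:
        seq = region.sequence
        methylated_pos = {site_map.site(i).sense_c_pos for i, v in vals.items() if v}
    else:
        seq = region.reverse_complement
        # antisense C sits opposite the sense G; its template coordinate is L - pos + 1
        methylated_pos = {length - site_map.site(i).antisense_c_pos + 1
                          for i, v in vals.items() if v}
    out = []
    for pos0, base in enumerate(seq):
        if base == "C" and (pos0 + 1) not in methylated_pos:
            out.append("T")
        else:
            out.append(base)
    converted = "".join(out)
    template = BisulfiteTemplate(strand, converted, state)
    unreadable = flag_unreadable_sites(template, site_map, min_run_length)
    return BisulfiteTemplate(strand, converted, state, frozenset(unreadable))


def _homopolymer_t_runs(seq: str, min_len: int) -> list[tuple[int, int]]:
    """0-based inclusive (start, end) of every T run of length >= min_len."""
    return [(m.start(), m.end() - 1) for m in re.finditer(r"T{%d,}" % min_len, seq)]


def flag_unreadable_sites(template: BisulfiteTemplate, site_map: CpGSiteMap,
                          min_run_length: int = 16) -> set[int]:
    """Sites read after the start of a poly-T run of the given length.

    The sequencing read traverses the region in ascending sense coordinate
    regardless of which strand's template is sequenced, so both strands use
    the sense-coordinate axis as the reading coordinate.  For the antisense
    template (stored reverse-complemented) run coordinates are mapped back
    onto that axis.
    """
    if min_run_length < 2:
        raise ValueError("min_run_length must be >= 2")
    seq = template.converted_sequence
    length = len(seq)
    runs = _homopolymer_t_runs(seq, min_run_length)
    if not runs:
        return set()
    if template.strand == SENSE:
        run_starts = [start0 + 1 for start0, _ in runs]
        site_read_pos = {s.index: s.sense_c_pos for s in site_map}
    else:
        # template string position q (1-based) maps to sense coordinate L - q + 1;
        # the first template base of a run is its string *end* on the sense axis
        run_starts = [length - end0 for _, end0 in runs]
        site_read_pos = {s.index: s.antisense_c_pos for s in site_map}
    first = min(run_starts)
    return {i for i, pos in site_read_pos.items() if pos > first}
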