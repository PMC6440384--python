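"""Germline TRG/TRD segment reference: loading, validation and lookup.

The human γ/δ T-cell receptor loci contain 14 unique Vγ segments (TRGV),
three unique Vδ segments (TRDV1-3) and five Vδ segments shared with the α
locus (TRDV4/TRAV14 ... TRDV8/TRAV38-2).  Segment records carry the two
junction anchors every annotation step depends on: the first nucleotide of
the conserved 2nd-CYS codon on V segments and the first nucleotide of the
conserved Phe/Trp codon of the J "[FW]-G-X-G" motif.  All coordinates are
0-based, half-open; anchors point at codon starts.

The bundled reference (``load_reference("builtin")``) is a *synthetic*
stand-in: sequences are generated, not IMGT records, but the locus
structure, segment nomenclature, anchor conventions and the
germline-encoded canonical Vγ9-JγP junction (C + ALWEVQELGKKIKV + F) are
faithful, so every downstream computation behaves as it would on the real
locus.  Constant genes carry the IMGT/LIGM-DB accessions of their real
counterparts as provenance notes.
"""
from __future__ import annotations

import difflib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

SEGMENT_TYPES = ("V", "D", "J", "C")
CHAINS = ("TRG", "TRD", "TRB", "TRA")

_META_COLUMNS = ["segment_id", "segment_type", "chain", "cys_anchor",
                 "fw_anchor", "functional", "source_accession"]


class ReferenceError(ValueError):
    """Raised when a reference fails structural validation."""


class SegmentNotFoundError(KeyError):
    """Raised when a segment id is absent from a ReferenceSet."""


@dataclass(frozen=True)
class GermlineSegment:
    """One V/D/J/C germline gene segment with junction-anchor metadata."""

    segment_id: str
    segment_type: str
    chain: str
    sequence: str
    cys_anchor: Optional[int] = None
    fw_anchor: Optional[int] = None
    functional: bool = True
    source_accession: str = ""

    def __post_init__(self) -> None:
        if self.segment_type not in SEGMENT_TYPES:
            raise ReferenceError(
                f"{self.segment_id}: bad segment_type {self.segment_type!r}")
        if self.chain not in CHAINS:
            raise ReferenceError(
                f"{self.segment_id}: bad chain {self.chain!r}")
        bad = set(self.sequence) - set("ACGT")
        if bad:
            raise ReferenceError(
                f"{self.segment_id}: non-ACGT characters {sorted(bad)}")

    def anchor_codon(self) -> Optional[str]:
        """The codon at the segment's junction anchor, if it has one."""
        pos = self.cys_anchor if self.segment_type == "V" else self.fw_anchor
        if pos is None:
            return None
        return self.sequence[pos:pos + 3]


@dataclass
class ReferenceSet:
    """A validated collection of germline segments for annotation and
    constant-region quantification."""

    segments: list[GermlineSegment]
    version: str = "synthetic-1"
    _index: dict[str, GermlineSegment] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._index = {}
        for seg in self.segments:
            key = seg.segment_id.upper()
            if key in self._index:
                raise ReferenceError(f"duplicate segment_id {seg.segment_id}")
            self._index[key] = seg
        # shared Vδ/Vα ids are addressable by their TRDV alias too
        for seg in self.segments:
            if "/" in seg.segment_id:
                alias = seg.segment_id.split("/", 1)[0].upper()
                self._index.setdefault(alias, seg)

    # -- lookup ------------------------------------------------------------
    def get_segment(self, segment_id: str) -> GermlineSegment:
        seg = self._index.get(segment_id.upper())
        if seg is None:
            near = difflib.get_close_matches(
                segment_id.upper(), list(self._index), n=3)
            raise SegmentNotFoundError(
                f"unknown segment {segment_id!r}; nearest: {near}")
        return seg

    def __contains__(self, segment_id: str) -> bool:
        return segment_id.upper() in self._index

    def by_type(self, segment_type: str, chain: Optional[str] = None
                ) -> list[GermlineSegment]:
        return [s for s in self.segments
                if s.segment_type == segment_type
                and (chain is None or s.chain == chain)]

    @property
    def constant_genes(self) -> list[GermlineSegment]:
        return self.by_type("C")

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        """Check anchor translation and locus-count invariants; raise
        ReferenceError naming the first offending segment."""
        for seg in self.segments:
            if seg.segment_type == "V" and seg.functional:
                if seg.cys_anchor is None:
                    raise ReferenceError(
                        f"{seg.segment_id}: functional V without cys_anchor")
                if str(Seq(seg.anchor_codon()).translate()) != "C":
                    raise ReferenceError(
                        f"{seg.segment_id}: cys_anchor codon "
                        f"{seg.anchor_codon()!r} does not encode C")
            if seg.segment_type == "J" and seg.functional:
                if seg.fw_anchor is None:
                    raise ReferenceError(
                        f"{seg.segment_id}: functional J without fw_anchor")
                motif = str(Seq(
                    seg.sequence[seg.fw_anchor:seg.fw_anchor + 12]
                ).translate())
                if len(motif) < 4 or motif[0] not in "FW" \
                        or motif[1] != "G" or motif[3] != "G":
                    raise ReferenceError(
                        f"{seg.segment_id}: no [FW]GXG motif at fw_anchor "
                        f"(got {motif!r})")
        n_trgv = len(self.by_type("V", "TRG"))
        if n_trgv != 14:
            raise ReferenceError(f"expected 14 TRG V segments, got {n_trgv}")
        for sid in ("TRDV1", "TRDV2", "TRDV3", "TRGC1", "TRGC2"):
            if sid not in self:
                raise ReferenceError(f"missing required segment {sid}")
        shared = [s for s in self.by_type("V", "TRD") if "/" in s.segment_id]
        if len(shared) != 5:
            raise ReferenceError(
                f"expected 5 shared Vδ/Vα segments, got {len(shared)}")
        c_chains = {s.chain for s in self.constant_genes}
        missing = {"TRA", "TRB", "TRG", "TRD"} - c_chains
        if missing:
            raise ReferenceError(
                f"constant genes missing for chains {sorted(missing)}")

    # -- I/O ---------------------------------------------------------------
    def write(self, fasta_path: str | Path, meta_path: str | Path) -> None:
        """Write sequences to FASTA and anchor metadata to a TSV table."""
        with open(fasta_path, "w") as fa:
            for seg in self.segments:
                fa.write(f">{seg.segment_id}\n{seg.sequence}\n")
        rows = [{
            "segment_id": s.segment_id,
            "segment_type": s.segment_type,
            "chain": s.chain,
            "cys_anchor": "" if s.cys_anchor is None else s.cys_anchor,
            "fw_anchor": "" if s.fw_anchor is None else s.fw_anchor,
            "functional": str(s.functional).lower(),
            "source_accession": s.source_accession,
        } for s in self.segments]
        pd.DataFrame(rows, columns=_META_COLUMNS).to_csv(
            meta_path, sep="\t", index=False)


def _builtin_paths() -> tuple[Path, Path]:
    root = resources.files("gdrep") / "data"
    return (Path(str(root / "synthetic_trgd.fasta")),
            Path(str(root / "synthetic_trgd_meta.tsv")))


def load_reference(path_or_builtin: str = "builtin",
                   meta_path: Optional[str | Path] = None) -> ReferenceSet:
    """Load and validate a germline reference.

    Parameters
    ----------
    path_or_builtin:
        ``"builtin"`` for the packaged synthetic TRG/TRD reference, or a
        FASTA path (then ``meta_path`` must point at the segment-metadata
        TSV, or defaults to the FASTA path with a ``_meta.tsv`` suffix).
    """
    if path_or_builtin == "builtin":
        fasta_path, meta = _builtin_paths()
        version = "synthetic-1"
    else:
        fasta_path = Path(path_or_builtin)
        meta = Path(meta_path) if meta_path is not None else \
            fasta_path.with_name(fasta_path.stem + "_meta.tsv")
        version = fasta_path.name
    if not fasta_path.exists():
        raise FileNotFoundError(fasta_path)
    if not meta.exists():
        raise FileNotFoundError(meta)

    seqs = {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(fasta_path), "fasta")}
    table = pd.read_csv(meta, sep="\t", dtype=str, keep_default_na=False)
    missing_cols = set(_META_COLUMNS) - set(table.columns)
    if missing_cols:
        raise ReferenceError(f"metadata missing columns {sorted(missing_cols)}")

    segments = []
    for row in table.itertuples(index=False):
        if row.segment_id not in seqs:
            raise ReferenceError(
                f"{row.segment_id}: in metadata but not in FASTA")
        segments.append(GermlineSegment(
            segment_id=row.segment_id,
            segment_type=row.segment_type,
            chain=row.chain,
            sequence=seqs[row.segment_id],
            cys_anchor=int(row.cys_anchor) if row.cys_anchor != "" else None,
            fw_anchor=int(row.fw_anchor) if row.fw_anchor != "" else None,
            functional=row.functional.strip().lower() == "true",
            source_accession=row.source_accession,
        ))
    extra = set(seqs) - {s.segment_id for s in segments}
    if extra:
        raise ReferenceError(f"FASTA entries without metadata: {sorted(extra)}")
    ref = ReferenceSet(segments=segments, version=version)
    ref.validate()
    return ref


def get_segment(ref: ReferenceSet, segment_id: str) -> GermlineSegment:
    """Case-insensitive segment lookup (module-level convenience)."""
    return ref.get_segment(segment_id)
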