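"""Cross-compartment clonotype comparison and canonical-rearrangement
classification.

Blood γδ T cells are dominated by the public canonical Vγ9-JγP
rearrangement (read through the Cγ1 constant exon); Vγ9-Jγ2
rearrangements imply Cγ2 use by locus order (JγP1-JγP-Jγ1-Cγ1 precede
JγP2-Jγ2-Cγ2, so a Jγ2 join can only splice to Cγ2).  The constant-gene
call is therefore an *inference* from the J segment, never a sequence
observation — amplicons rarely reach the C exon — and is labelled as such
in outputs.  The JγP lysine anchor (the K of the germline "KIKV" CDR3
suffix, critical for phosphoantigen recognition) is tested as a J-suffix
motif, a deliberate simplification of full IMGT position-109 numbering.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Optional, Sequence

from Bio.Seq import Seq

from .clonostats import (Repertoire, jensen_shannon_divergence,
                         shannon_index, vj_usage)
from .reference import ReferenceSet

# J segments upstream of each TRG constant exon, in locus order
_CGAMMA1_JS = {"TRGJP1", "TRGJP", "TRGJ1"}
_CGAMMA2_JS = {"TRGJP2", "TRGJ2"}
JP_LYS_SUFFIX = "KIKV"  # germline JγP CDR3 tail carrying the critical Lys


@dataclass
class ClonotypeRecord:
    """One amino-acid clonotype row of a Table-3-style top-N report."""

    cdr3_aa: str
    v_call: str
    j_call: str
    pct_within_vj: float
    pct_total: float
    rank_within_vj: int


@dataclass
class CanonicalCall:
    category: str  # canonical_Vg9JgP | noncanonical_Vg9Jg2 | other
    inferred_c_gene: str  # TRGC1 | TRGC2 | unknown
    has_jp_lys_anchor: bool


def top_clonotypes(rep: Repertoire, v_call: str, j_call: str,
                   n: int = 10) -> list[ClonotypeRecord]:
    """Top-n amino-acid clonotypes of one V-J pair.

    Nucleotide clonotypes translating to the same CDR3 within the pair
    are merged.  ``pct_within_vj`` is the share among (productive) reads
    of that V-J pair; ``pct_total`` the share of all clean same-chain
    reads.  Sorted by pct_within_vj descending, ties broken
    lexicographically by cdr3_aa.  An absent pair yields an empty list.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    total = rep.cnt
    aa_counts: dict[str, int] = {}
    for (junction, v, j), count in rep.clonotypes.items():
        if v != v_call or j != j_call:
            continue
        if len(junction) % 3 != 0 or len(junction) < 9:
            continue
        aa = str(Seq(junction).translate())
        if "*" in aa:
            continue
        cdr3 = aa[1:-1]
        aa_counts[cdr3] = aa_counts.get(cdr3, 0) + count
    group_total = sum(aa_counts.values())
    if group_total == 0:
        return []
    ranked = sorted(aa_counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [ClonotypeRecord(
        cdr3_aa=cdr3,
        v_call=v_call,
        j_call=j_call,
        pct_within_vj=100.0 * c / group_total,
        pct_total=100.0 * c / total,
        rank_within_vj=i + 1,
    ) for i, (cdr3, c) in enumerate(ranked[:n])]


def classify_rearrangement(v_call: str, j_call: str, cdr3_aa: str,
                           ref: ReferenceSet) -> CanonicalCall:
    """Canonical Vγ9JγP vs non-canonical Vγ9Jγ2 classification with
    constant-gene inference.  Pure function of its inputs."""
    v = ref.get_segment(v_call)  # raises on unknown ids
    j = ref.get_segment(j_call)
    if v.segment_id == "TRGV9" and j.segment_id == "TRGJP":
        category = "canonical_Vg9JgP"
    elif v.segment_id == "TRGV9" and j.segment_id == "TRGJ2":
        category = "noncanonical_Vg9Jg2"
    else:
        category = "other"
    if j.segment_id in _CGAMMA1_JS:
        c_gene = "TRGC1"
    elif j.segment_id in _CGAMMA2_JS:
        c_gene = "TRGC2"
    else:
        c_gene = "unknown"
    return CanonicalCall(
        category=category,
        inferred_c_gene=c_gene,
        has_jp_lys_anchor=cdr3_aa.endswith(JP_LYS_SUFFIX))


@dataclass
class SharedExclusive:
    """Partition of the union of clonotype keys across two compartments;
    each entry maps key -> (blood frequency, tumor frequency)."""

    shared: dict
    blood_only: dict
    tumor_only: dict
    level: str


def shared_exclusive(rep_blood: Repertoire, rep_tumor: Repertoire,
                     level: str = "nt") -> SharedExclusive:
    """Shared and compartment-exclusive clonotypes at nucleotide or
    amino-acid level; the three sets partition the key union."""
    if rep_blood.chain != rep_tumor.chain:
        raise ValueError("chain mismatch")
    if level not in ("nt", "aa"):
        raise ValueError("level must be 'nt' or 'aa'")

    def collapse(rep: Repertoire) -> dict:
        if level == "nt":
            return rep.frequencies()
        out: dict = {}
        total = rep.cnt
        for (junction, v, j), c in rep.clonotypes.items():
            if len(junction) % 3 != 0 or len(junction) < 9:
                continue
            aa = str(Seq(junction).translate())
            if "*" in aa:
                continue
            key = (aa[1:-1], v, j)
            out[key] = out.get(key, 0.0) + c / total
        return out

    fb, ft = collapse(rep_blood), collapse(rep_tumor)
    shared, blood_only, tumor_only = {}, {}, {}
    for k in set(fb) | set(ft):
        pair = (fb.get(k, 0.0), ft.get(k, 0.0))
        if k in fb and k in ft:
            shared[k] = pair
        elif k in fb:
            blood_only[k] = pair
        else:
            tumor_only[k] = pair
    return SharedExclusive(shared=shared, blood_only=blood_only,
                           tumor_only=tumor_only, level=level)


REPORT_SCHEMA_VERSION = "1.0"


def _key_str(key) -> str:
    return "|".join(key) if isinstance(key, tuple) else str(key)


def compartment_report(pairs: Sequence[tuple[Repertoire,
                                             Optional[Repertoire]]],
                       ref: ReferenceSet) -> dict:
    """Structured blood/tumor comparison report for one or more pairs.

    Per pair: Shannon index for both compartments, JSD, V-J usage
    matrices, top-10 tables for Vγ9JγP and Vγ9Jγ2 in each compartment and
    a shared/exclusive summary.  JSON-serialisable; incomplete pairs
    (missing tumor) are flagged rather than dropped.
    """
    if not pairs:
        raise ValueError("at least one blood/tumor pair required")
    report: dict = {"schema_version": REPORT_SCHEMA_VERSION, "pairs": []}
    for blood, tumor in pairs:
        entry: dict = {"sample_id": blood.sample_id, "chain": blood.chain,
                       "complete": tumor is not None}
        entry["blood"] = _compartment_block(blood, ref)
        if tumor is None:
            report["pairs"].append(entry)
            continue
        entry["tumor"] = _compartment_block(tumor, ref)
        entry["jsd"] = jensen_shannon_divergence(blood, tumor).jsd
        se = shared_exclusive(blood, tumor, level="nt")
        entry["overlap"] = {
            "n_shared": len(se.shared),
            "n_blood_only": len(se.blood_only),
            "n_tumor_only": len(se.tumor_only),
        }
        report["pairs"].append(entry)
    return report


def _compartment_block(rep: Repertoire, ref: ReferenceSet) -> dict:
    usage = vj_usage(rep)
    block = {
        "sample_id": rep.sample_id,
        "compartment": rep.compartment,
        "cnt": rep.cnt,
        "cnu": rep.cnu,
        "shannon": shannon_index(rep).shannon,
        "vj_usage": {v: {j: float(usage.loc[v, j]) for j in usage.columns
                         if usage.loc[v, j] > 0}
                     for v in usage.index},
    }
    for j_call, label in (("TRGJP", "top10_Vg9JgP"),
                          ("TRGJ2", "top10_Vg9Jg2")):
        if rep.chain == "TRG":
            records = top_clonotypes(rep, "TRGV9", j_call, n=10)
            block[label] = [dict(asdict(r), **asdict(
                classify_rearrangement(r.v_call, r.j_call, r.cdr3_aa, ref)))
                for r in records]
    return block


def report_to_json(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")


def report_from_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def report_to_text(report: dict) -> str:
    """Human-readable rendering of a comparison report."""
    lines = [f"γδ TCR repertoire comparison (schema "
             f"{report['schema_version']})"]
    for pair in report["pairs"]:
        lines.append(f"\n== {pair['sample_id']} ({pair['chain']}) ==")
        for comp in ("blood", "tumor"):
            if comp not in pair:
                lines.append(f"  {comp}: MISSING (pair incomplete)")
                continue
            b = pair[comp]
            lines.append(
                f"  {comp}: CNT={b['cnt']} CNU={b['cnu']} "
                f"Shannon={b['shannon']:.3f}")
            for label in ("top10_Vg9JgP", "top10_Vg9Jg2"):
                for r in b.get(label, [])[:3]:
                    lines.append(
                        f"    {label[6:]} #{r['rank_within_vj']} "
                        f"{r['cdr3_aa']}  {r['pct_within_vj']:.2f}% of V-J, "
                        f"{r['pct_total']:.2f}% of total "
                        f"[{r['inferred_c_gene']} inferred]")
        if "jsd" in pair:
            o = pair["overlap"]
            lines.append(
                f"  JSD={pair['jsd']:.4f}  shared={o['n_shared']} "
                f"blood-only={o['n_blood_only']} "
                f"tumor-only={o['n_tumor_only']}")
    return "\n".join(lines) + "\n"
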