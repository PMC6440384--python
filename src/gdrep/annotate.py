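"""Read annotation: Smith-Waterman V/J assignment, CDR3 junction
extraction and artifact filtering.

The aligner is a local (Smith-Waterman) aligner with affine gap penalties:
a gap of length L costs ``gap_open + (L-1)*gap_extend``.  Score ties are
broken by smallest read_start, then smallest ref_start.  The junction is
anchor-based: it spans from the read position aligned to the V segment's
conserved 2nd-CYS codon start through the end of the codon at the J
segment's [FW]GXG anchor, which makes extraction robust to chance
extension of the local alignment into N-region nucleotides.

Base qualities are ignored by the aligner; artifact filters are
sequence-level (documented limitation).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from numba import njit

from .reference import GermlineSegment, ReferenceSet

# default scoring; J segments are short, hence the lower J threshold
MATCH = 2
MISMATCH = -3
GAP_OPEN = 5
GAP_EXTEND = 2
MIN_SCORE_V = 40
MIN_SCORE_J = 20

_ENC = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGTN"):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def encode(seq: str, what: str = "sequence") -> np.ndarray:
    """Encode A/C/G/T/N to 0..4; any other character is an error naming
    the first bad offset."""
    if not seq:
        raise ValueError(f"empty {what}")
    arr = _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    bad = np.nonzero(arr < 0)[0]
    if bad.size:
        raise ValueError(
            f"invalid character {seq[bad[0]]!r} in {what} at offset {bad[0]}")
    return arr.astype(np.int8)


@dataclass
class AlignmentHit:
    """A local alignment of a read against one germline segment."""

    segment_id: str
    score: int
    read_start: int
    read_end: int
    ref_start: int
    ref_end: int
    identity: float
    # aligned (read, ref) position pairs for diagonal columns; used to map
    # germline anchors onto the read
    qpos: np.ndarray = field(default=None, repr=False)
    tpos: np.ndarray = field(default=None, repr=False)

    def read_pos_of(self, ref_pos: int) -> Optional[int]:
        """Read position aligned to ``ref_pos``, or None (gap/outside)."""
        idx = np.nonzero(self.tpos == ref_pos)[0]
        return int(self.qpos[idx[0]]) if idx.size else None


@njit(cache=True)
def _sw_score(q, t, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    n, m = q.shape[0], t.shape[0]
    NEG = -10**9
    h_prev = np.zeros(m + 1, dtype=np.int32)  # rolling H row
    f_col = np.full(m + 1, NEG, dtype=np.int32)  # rolling F per column
    best = 0
    for i in range(n):
        qi = q[i]
        e = NEG
        h_diag = 0  # H[i-1][j-1]
        h_left = 0  # H[i][j-1]
        for j in range(1, m + 1):
            e = max(h_left - gap_open, e - gap_extend)
            f = max(h_prev[j] - gap_open, f_col[j] - gap_extend)
            s = match if (qi == t[j - 1] and qi < 4) else mismatch
            h = h_diag + s
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            h_diag = h_prev[j]
            h_prev[j] = h
            h_left = h
            f_col[j] = f
            if h > best:
                best = h
    return best


@njit(cache=True)
def _sw_full(q, t, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    """Full DP with stored matrices; returns (H, E, F)."""
    n, m = q.shape[0], t.shape[0]
    NEG = -10**9
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    E = np.full((n + 1, m + 1), NEG, dtype=np.int32)
    F = np.full((n + 1, m + 1), NEG, dtype=np.int32)
    for i in range(1, n + 1):
        qi = q[i - 1]
        for j in range(1, m + 1):
            E[i, j] = max(H[i, j - 1] - gap_open, E[i, j - 1] - gap_extend)
            F[i, j] = max(H[i - 1, j] - gap_open, F[i - 1, j] - gap_extend)
            s = match if (qi == t[j - 1] and qi < 4) else mismatch
            h = H[i - 1, j - 1] + s
            if E[i, j] > h:
                h = E[i, j]
            if F[i, j] > h:
                h = F[i, j]
            if h < 0:
                h = 0
            H[i, j] = h
    return H, E, F


@njit(cache=True)
def _traceback(H, E, F, q, t, match, mismatch, gap_open, gap_extend,
               end_i, end_j):  # pragma: no cover
    """Trace one optimal path from (end_i, end_j); returns
    (start_i, start_j, qpos, tpos, n_ident, n_cols)."""
    i, j = end_i, end_j
    state = 0  # 0=H, 1=E (gap in read), 2=F (gap in ref)
    max_len = i + j
    qpos = np.empty(max_len, dtype=np.int32)
    tpos = np.empty(max_len, dtype=np.int32)
    k = 0
    n_ident = 0
    n_cols = 0
    while i > 0 and j > 0:
        if state == 0:
            if H[i, j] == 0:
                break
            s = match if (q[i - 1] == t[j - 1] and q[i - 1] < 4) else mismatch
            if H[i, j] == H[i - 1, j - 1] + s:
                qpos[k] = i - 1
                tpos[k] = j - 1
                k += 1
                n_cols += 1
                if q[i - 1] == t[j - 1] and q[i - 1] < 4:
                    n_ident += 1
                i -= 1
                j -= 1
            elif H[i, j] == F[i, j]:
                state = 2
            else:
                state = 1
        elif state == 1:  # E: consume target
            n_cols += 1
            if E[i, j] == H[i, j - 1] - gap_open:
                j -= 1
                state = 0
            else:
                j -= 1
        else:  # F: consume read
            n_cols += 1
            if F[i, j] == H[i - 1, j] - gap_open:
                i -= 1
                state = 0
            else:
                i -= 1
    return i, j, qpos[:k][::-1].copy(), tpos[:k][::-1].copy(), n_ident, n_cols


def smith_waterman(query: str, target: str, match: int = MATCH,
                   mismatch: int = MISMATCH, gap_open: int = GAP_OPEN,
                   gap_extend: int = GAP_EXTEND,
                   segment_id: str = "") -> AlignmentHit:
    """Optimal local alignment of ``query`` (read) against ``target``.

    Returns the maximal-score hit; among equal-score optima the one with
    the smallest read_start, then smallest ref_start, is reported.  N
    never matches anything (scored as a mismatch).
    """
    q = encode(query, "query")
    t = encode(target, "target")
    H, E, F = _sw_full(q, t, match, mismatch, gap_open, gap_extend)
    best = int(H.max())
    if best <= 0:
        return AlignmentHit(segment_id, 0, 0, 0, 0, 0, 0.0,
                            np.empty(0, np.int32), np.empty(0, np.int32))
    ends = np.argwhere(H == best)
    chosen = None
    for end_i, end_j in ends:
        si, sj, qp, tp, nid, ncol = _traceback(
            H, E, F, q, t, match, mismatch, gap_open, gap_extend,
            int(end_i), int(end_j))
        cand = (si, sj, int(end_i), int(end_j), qp, tp, nid, ncol)
        if chosen is None or cand[:4] < chosen[:4]:
            chosen = cand
    si, sj, ei, ej, qp, tp, nid, ncol = chosen
    return AlignmentHit(segment_id, best, si, ei, sj, ej,
                        nid / ncol if ncol else 0.0, qp, tp)


def _best_segment(q: np.ndarray, segments: Sequence[GermlineSegment],
                  encoded: dict[str, np.ndarray],
                  match: int, mismatch: int, gap_open: int, gap_extend: int
                  ) -> tuple[Optional[GermlineSegment], int]:
    best_seg, best_score = None, 0
    for seg in segments:
        sc = int(_sw_score(q, encoded[seg.segment_id],
                           match, mismatch, gap_open, gap_extend))
        if sc > best_score:
            best_seg, best_score = seg, sc
    return best_seg, best_score


class Annotator:
    """V/J caller for one chain of a reference set.

    Encodes the germline segments once; reads are scanned on the given
    strand and its reverse complement, and the orientation with the
    better summed V+J score wins (ties: given strand).
    """

    def __init__(self, ref: ReferenceSet, chain: str,
                 match: int = MATCH, mismatch: int = MISMATCH,
                 gap_open: int = GAP_OPEN, gap_extend: int = GAP_EXTEND,
                 min_score_v: int = MIN_SCORE_V,
                 min_score_j: int = MIN_SCORE_J):
        self.ref = ref
        self.chain = chain
        self.params = (match, mismatch, gap_open, gap_extend)
        self.min_score_v = min_score_v
        self.min_score_j = min_score_j
        self.v_segments = ref.by_type("V", chain)
        self.j_segments = ref.by_type("J", chain)
        if not self.v_segments or not self.j_segments:
            raise ValueError(f"reference has no V or J segments for {chain}")
        self._enc = {s.segment_id: encode(s.sequence)
                     for s in self.v_segments + self.j_segments}

    def _align_strand(self, read: str):
        q = encode(read, "read")
        vseg, vscore = _best_segment(q, self.v_segments, self._enc,
                                     *self.params)
        v_hit = None
        if vseg is not None and vscore >= self.min_score_v:
            v_hit = smith_waterman(read, vseg.sequence, *self.params,
                                   segment_id=vseg.segment_id)
        j_hit = None
        offset = v_hit.read_end if v_hit else 0
        tail = read[offset:]
        if tail:
            qj = q[offset:]
            jseg, jscore = _best_segment(qj, self.j_segments, self._enc,
                                         *self.params)
            if jseg is not None and jscore >= self.min_score_j:
                j_hit = smith_waterman(tail, jseg.sequence, *self.params,
                                       segment_id=jseg.segment_id)
                j_hit.read_start += offset
                j_hit.read_end += offset
                j_hit.qpos = j_hit.qpos + offset
        total = (v_hit.score if v_hit else 0) + (j_hit.score if j_hit else 0)
        return v_hit, j_hit, total

    def assign_vj(self, read: str):
        """Best V and J hits with non-overlapping read intervals, plus the
        oriented read.  No-call (None) is a value, not an error."""
        fwd = self._align_strand(read)
        rc = revcomp(read)
        rev = self._align_strand(rc)
        if rev[2] > fwd[2]:
            return rev[0], rev[1], rc
        return fwd[0], fwd[1], read


@dataclass
class Rearrangement:
    """One annotated read."""

    read_id: str
    v_call: Optional[str]
    j_call: Optional[str]
    junction_nt: str
    junction_aa: str
    cdr3_aa: str
    productive: bool
    vj_in_frame: bool
    stop_codon: bool
    pass_qc: bool
    qc_reason: str = ""
    v_hit: Optional[AlignmentHit] = None
    j_hit: Optional[AlignmentHit] = None


def extract_junction(read: str, v_hit: AlignmentHit, j_hit: AlignmentHit,
                     ref: ReferenceSet, read_id: str = "") -> Rearrangement:
    """Extract the CDR3 junction given V and J hits.

    The junction runs from the read position aligned to the V cys anchor
    through the last base of the J [FW] anchor codon, inclusive of both
    conserved codons.  ``cdr3_aa`` strips the flanking C and F/W.  If an
    anchor falls outside (or in a gap of) the aligned region the read is
    kept but flagged ``pass_qc=False`` with a reason code.
    """
    vseg = ref.get_segment(v_hit.segment_id)
    jseg = ref.get_segment(j_hit.segment_id)

    def fail(reason: str) -> Rearrangement:
        return Rearrangement(read_id, vseg.segment_id, jseg.segment_id,
                             "", "", "", False, False, False,
                             pass_qc=False, qc_reason=reason,
                             v_hit=v_hit, j_hit=j_hit)

    if vseg.cys_anchor is None:
        return fail("v_no_anchor")
    if jseg.fw_anchor is None:
        return fail("j_no_anchor")
    start = v_hit.read_pos_of(vseg.cys_anchor)
    if start is None:
        return fail("v_anchor_outside")
    end = j_hit.read_pos_of(jseg.fw_anchor + 2)
    if end is None:
        return fail("j_anchor_outside")
    junction_nt = read[start:end + 1]
    in_frame = len(junction_nt) % 3 == 0 and len(junction_nt) >= 6
    junction_aa = ""
    cdr3_aa = ""
    stop = False
    if in_frame:
        junction_aa = str(Seq(junction_nt).translate())
        stop = "*" in junction_aa
        cdr3_aa = junction_aa[1:-1]
    productive = in_frame and not stop
    return Rearrangement(read_id, vseg.segment_id, jseg.segment_id,
                         junction_nt, junction_aa, cdr3_aa,
                         productive, in_frame, stop,
                         pass_qc=True, v_hit=v_hit, j_hit=j_hit)


def annotate_reads(reads: Iterable[tuple[str, str]], ref: ReferenceSet,
                   chain: str, **kwargs) -> list[Rearrangement]:
    """Annotate (read_id, sequence) pairs; returns one Rearrangement per
    read, no-calls included (pass_qc=False, reason "no_call")."""
    ann = Annotator(ref, chain, **kwargs)
    out = []
    for read_id, seq in reads:
        v_hit, j_hit, oriented = ann.assign_vj(seq)
        if v_hit is None or j_hit is None:
            out.append(Rearrangement(
                read_id,
                v_hit.segment_id if v_hit else None,
                j_hit.segment_id if j_hit else None,
                "", "", "", False, False, False,
                pass_qc=False, qc_reason="no_call",
                v_hit=v_hit, j_hit=j_hit))
        else:
            out.append(extract_junction(oriented, v_hit, j_hit, ref,
                                        read_id=read_id))
    return out


def filter_artifacts(rearrangements: Sequence[Rearrangement],
                     min_score: int = 0, min_junction_aa: int = 5,
                     max_junction_aa: int = 35
                     ) -> tuple[list[Rearrangement], dict]:
    """Remove artifact reads; survivors are the "clean" (CNT) population.

    Removes no-calls and anchor failures, hits under ``min_score``, and
    junctions whose CDR3 length in amino acids falls outside
    [min_junction_aa, max_junction_aa].  Returns (survivors, QC report);
    the report counts removals per reason.
    """
    kept: list[Rearrangement] = []
    reasons: dict[str, int] = {}

    def drop(reason: str) -> None:
        reasons[reason] = reasons.get(reason, 0) + 1

    for r in rearrangements:
        if not r.pass_qc:
            drop(r.qc_reason or "no_call")
            continue
        if (r.v_hit and r.v_hit.score < min_score) or \
                (r.j_hit and r.j_hit.score < min_score):
            drop("low_score")
            continue
        cdr3_len = len(r.junction_nt) // 3 - 2
        if not (min_junction_aa <= cdr3_len <= max_junction_aa):
            drop("junction_length")
            continue
        kept.append(r)
    report = {
        "input": len(rearrangements),
        "passed": len(kept),
        "removed": reasons,
        "min_score": min_score,
        "junction_aa_range": [min_junction_aa, max_junction_aa],
    }
    return kept, report


def to_airr(rearrangements: Sequence[Rearrangement]) -> pd.DataFrame:
    """AIRR Rearrangement table (TSV-ready)."""
    rows = [{
        "sequence_id": r.read_id,
        "v_call": r.v_call or "",
        "d_call": "",
        "j_call": r.j_call or "",
        "junction": r.junction_nt,
        "junction_aa": r.junction_aa,
        "productive": r.productive,
        "vj_in_frame": r.vj_in_frame,
        "stop_codon": r.stop_codon,
        "consensus_count": 1,
    } for r in rearrangements]
    return pd.DataFrame(rows, columns=[
        "sequence_id", "v_call", "d_call", "j_call", "junction",
        "junction_aa", "productive", "vj_in_frame", "stop_codon",
        "consensus_count"])
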