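"""Clonotype aggregation and repertoire statistics.

A clonotype is keyed by (junction nucleotide sequence, V call, J call) —
amino-acid collapsing happens only in reporting.  The module computes the
CNT/CNU accounting (total vs unique clean sequences), the Shannon index
H = −Σ pᵢ·log₂ pᵢ (base-2 by default, so H is in bits and JSD's upper
bound of 1 means completely disjoint repertoires), the Jensen-Shannon
divergence JSD(P,Q) = ½ KL(P‖M) + ½ KL(Q‖M) with M = (P+Q)/2 over the
union of clonotype keys, V-J segment usage matrices, junction-feature
distributions and squarified treemap layouts.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .annotate import Rearrangement
from .simulate import SimTruth

ClonotypeKey = tuple[str, str, str]  # (junction_nt, v_call, j_call)


@dataclass
class Repertoire:
    """One sample's clonotype frequency table."""

    sample_id: str
    compartment: str  # blood | tumor | other
    chain: str
    clonotypes: dict[ClonotypeKey, int]

    @property
    def cnt(self) -> int:
        """Total clean nucleotide sequences."""
        return sum(self.clonotypes.values())

    @property
    def cnu(self) -> int:
        """Unique clean nucleotide sequences (clonotype richness)."""
        return len(self.clonotypes)

    def frequencies(self) -> dict[ClonotypeKey, float]:
        total = self.cnt
        return {k: c / total for k, c in self.clonotypes.items()}


@dataclass
class DiversityReport:
    shannon: float
    richness: int
    evenness: float
    log_base: float = 2.0


@dataclass
class DivergenceReport:
    jsd: float
    shared_clonotypes: int
    support_union: int


def build_repertoire(rearrangements: Sequence[Rearrangement],
                     sample_id: str, compartment: str = "other",
                     chain: Optional[str] = None) -> Repertoire:
    """Group QC-passing rearrangements into clonotypes.

    Raises on an empty repertoire or duplicate read ids.
    """
    seen_ids: set[str] = set()
    counts: dict[ClonotypeKey, int] = {}
    for r in rearrangements:
        if r.read_id in seen_ids:
            raise ValueError(f"duplicate read_id {r.read_id}")
        seen_ids.add(r.read_id)
        if not r.pass_qc:
            continue
        key = (r.junction_nt, r.v_call, r.j_call)
        counts[key] = counts.get(key, 0) + 1
    if not counts:
        raise ValueError("empty repertoire")
    if chain is None:
        chain = "TRG" if next(iter(counts))[1].startswith("TRG") else "TRD"
    return Repertoire(sample_id=sample_id, compartment=compartment,
                      chain=chain, clonotypes=counts)


def repertoire_from_truth(truth: Sequence[SimTruth], sample_id: str,
                          compartment: str = "other",
                          chain: str = "TRG") -> Repertoire:
    """Ground-truth repertoire (in-window reads only) for recovery tests."""
    counts: dict[ClonotypeKey, int] = {}
    for t in truth:
        if not t.in_window:
            continue
        key = (t.junction_nt, t.v_id, t.j_id)
        counts[key] = counts.get(key, 0) + 1
    if not counts:
        raise ValueError("empty repertoire")
    return Repertoire(sample_id, compartment, chain, counts)


def repertoire_from_airr(path_or_df, sample_id: str,
                         compartment: str = "other") -> Repertoire:
    """Build a Repertoire from an AIRR rearrangement TSV (or DataFrame)
    of clean reads, keyed by (junction, v_call, j_call)."""
    df = path_or_df if isinstance(path_or_df, pd.DataFrame) \
        else pd.read_csv(path_or_df, sep="\t", dtype=str,
                         keep_default_na=False)
    counts: dict[ClonotypeKey, int] = {}
    chain = None
    for row in df.itertuples(index=False):
        if not row.junction or not row.v_call or not row.j_call:
            continue
        key = (row.junction, row.v_call, row.j_call)
        counts[key] = counts.get(key, 0) + 1
        if chain is None:
            chain = "TRG" if row.v_call.startswith("TRG") else "TRD"
    if not counts:
        raise ValueError("empty repertoire")
    return Repertoire(sample_id, compartment, chain, counts)


def shannon_index(rep: Repertoire, log_base: float = 2.0) -> DiversityReport:
    """Shannon diversity H = −Σ pᵢ log(pᵢ); evenness H / log(richness)
    (0 for a single clonotype)."""
    p = np.array(list(rep.clonotypes.values()), dtype=float)
    p = p / p.sum()
    h = float(-(p * (np.log(p) / math.log(log_base))).sum())
    h = max(h, 0.0)
    richness = rep.cnu
    evenness = h / (math.log(richness) / math.log(log_base)) \
        if richness > 1 else 0.0
    return DiversityReport(shannon=h, richness=richness, evenness=evenness,
                           log_base=log_base)


def jensen_shannon_divergence(rep_a: Repertoire, rep_b: Repertoire
                              ) -> DivergenceReport:
    """Base-2 Jensen-Shannon divergence over the union of clonotype keys.

    0 iff the frequency maps are identical; exactly 1 iff the supports
    are disjoint.
    """
    if rep_a.chain != rep_b.chain:
        raise ValueError(
            f"chain mismatch: {rep_a.chain} vs {rep_b.chain}")
    fa, fb = rep_a.frequencies(), rep_b.frequencies()
    union = sorted(set(fa) | set(fb))
    p = np.array([fa.get(k, 0.0) for k in union])
    q = np.array([fb.get(k, 0.0) for k in union])
    m = 0.5 * (p + q)

    def kl(x, y):
        mask = x > 0
        return float(np.sum(x[mask] * np.log2(x[mask] / y[mask])))

    jsd = 0.5 * kl(p, m) + 0.5 * kl(q, m)
    jsd = min(max(jsd, 0.0), 1.0)
    shared = sum(1 for k in fa if k in fb)
    return DivergenceReport(jsd=jsd, shared_clonotypes=shared,
                            support_union=len(union))


def vj_usage(rep: Repertoire, weight: str = "reads") -> pd.DataFrame:
    """V-J combination usage matrix (rows V, columns J); entries sum to 1.

    weight="reads" uses read counts, "clonotypes" counts each clonotype
    key once.
    """
    if weight not in ("reads", "clonotypes"):
        raise ValueError("weight must be 'reads' or 'clonotypes'")
    rows = [{"v_call": v, "j_call": j,
             "w": c if weight == "reads" else 1}
            for (junction, v, j), c in rep.clonotypes.items()]
    df = pd.DataFrame(rows)
    mat = df.pivot_table(index="v_call", columns="j_call", values="w",
                         aggfunc="sum", fill_value=0).astype(float)
    return mat / mat.values.sum()


def v_usage(rep: Repertoire, weight: str = "reads") -> pd.Series:
    """Per-V-segment usage (marginal of the V-J matrix)."""
    return vj_usage(rep, weight).sum(axis=1)


@dataclass
class JunctionProfiles:
    """Histogram bundle for CDR3 length and junctional modifications."""

    cdr3_aa_length: pd.Series
    trimmed_nt: pd.Series
    inserted_nt: pd.Series


def _hist(values: Iterable[int]) -> pd.Series:
    values = list(values)
    if not values:
        return pd.Series(dtype=int)
    counts = np.bincount(np.asarray(values, dtype=int))
    s = pd.Series(counts, index=np.arange(len(counts)))
    return s[s > 0]


def junction_profiles(rearrangements: Sequence[Rearrangement] = (),
                      truth: Sequence[SimTruth] = ()) -> JunctionProfiles:
    """Distributions of CDR3 amino-acid length (from rearrangements
    and/or truth) and of trimmed/inserted nucleotides (truth only — the
    annotator does not decompose the N region)."""
    lengths = [len(r.cdr3_aa) for r in rearrangements if r.cdr3_aa]
    lengths += [len(t.junction_aa) - 2 for t in truth
                if t.in_frame and len(t.junction_aa) >= 2]
    trims = []
    inserts = []
    for t in truth:
        trims.append(t.v_trim + t.j_trim + t.d_trim5 + t.d_trim3)
        inserts.append(len(t.n1_insert) + len(t.n2_insert))
    return JunctionProfiles(cdr3_aa_length=_hist(lengths),
                            trimmed_nt=_hist(trims),
                            inserted_nt=_hist(inserts))


# ---------------------------------------------------------------- treemap


@dataclass
class TreemapRect:
    key: ClonotypeKey
    frequency: float
    x: float
    y: float
    w: float
    h: float


def _worst_ratio(row: list[float], length: float) -> float:
    """Worst rectangle aspect ratio if ``row`` is laid along a side of
    the given length (standard squarify criterion)."""
    s = sum(row)
    if s == 0 or length == 0:
        return float("inf")
    l2 = length * length
    return max(
        max(l2 * v / (s * s), s * s / (l2 * v)) if v > 0 else float("inf")
        for v in row)


def _squarify(areas: list[float], x: float, y: float, w: float, h: float,
              out: list[tuple[float, float, float, float]]) -> None:
    """Squarified treemap (Bruls-Huizing-van Wijk): greedily grow a row
    along the shorter side while the worst aspect ratio improves."""
    areas = list(areas)
    while areas:
        length = min(w, h)
        row = [areas.pop(0)]
        while areas:
            if _worst_ratio(row + [areas[0]], length) <= _worst_ratio(
                    row, length):
                row.append(areas.pop(0))
            else:
                break
        s = sum(row)
        if w >= h:  # lay row vertically along the left edge
            rw = s / h if h > 0 else 0.0
            cy = y
            for v in row:
                rh = v / rw if rw > 0 else 0.0
                out.append((x, cy, rw, rh))
                cy += rh
            x += rw
            w -= rw
        else:  # lay row horizontally along the top edge
            rh = s / w if w > 0 else 0.0
            cx = x
            for v in row:
                rw = v / rh if rh > 0 else 0.0
                out.append((cx, y, rw, rh))
                cx += rw
            y += rh
            h -= rh


def treemap_weights(rep: Repertoire) -> list[TreemapRect]:
    """Squarified treemap of clonotype frequencies in the unit square:
    rectangle areas are proportional to frequencies and tile [0,1]²."""
    items = sorted(rep.frequencies().items(),
                   key=lambda kv: (-kv[1], kv[0]))
    areas = [f for _, f in items]
    rects: list[tuple[float, float, float, float]] = []
    _squarify(areas, 0.0, 0.0, 1.0, 1.0, rects)
    return [TreemapRect(key=k, frequency=f, x=r[0], y=r[1], w=r[2], h=r[3])
            for (k, f), r in zip(items, rects)]
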