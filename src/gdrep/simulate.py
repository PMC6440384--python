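"""V(D)J recombination and amplicon-read simulator with ground truth.

Generative model, per clonotype: pick V and J (TRD: plus one D) from the
configured usage distributions; trim each joined segment end by a
Geometric(mean=trim_mean) number of nucleotides (support 0,1,2,...); add
Poisson(n_insert_mean)-length N regions with uniform base composition
(TRG: one N region; TRD: two, flanking the D segment).  Clonotype
frequencies are drawn once per run from a symmetric Dirichlet — a small
concentration gives an oligoclonal repertoire.  Reads cover an amplicon
window (default: the final 60 nt of the trimmed V through the first 40 nt
of the trimmed J) with per-base substitution errors and constant Q30
qualities.  Out-of-frame rearrangements arise at the rate junction
arithmetic implies and are flagged, never discarded.

``blood_tumor_scenario`` builds the paired sample structures the analysis
is designed around: a blood-like repertoire dominated by the public
canonical Vγ9-JγP clonotype, a tumor-like repertoire whose dominant
clonotypes are non-canonical Vγ9-Jγ2, and an oligoclonal pair with
forced-disjoint clonotype sets (one clonotype >= 95% of blood reads).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
from Bio.Seq import Seq

from .reference import ReferenceSet

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# the public germline-encoded canonical rearrangement
CANONICAL_V = "TRGV9"
CANONICAL_J = "TRGJP"


@dataclass
class SimulationConfig:
    chain: str = "TRG"
    n_reads: int = 1000
    v_usage: dict[str, float] = field(default_factory=dict)
    j_usage: dict[str, float] = field(default_factory=dict)
    n_clonotypes: int = 100
    clonotype_concentration: float = 1.0
    trim_mean: float = 2.0
    n_insert_mean: float = 4.0
    error_rate: float = 0.0
    canonical_spike: float = 0.0
    seed: int = 0
    v_window: int = 60
    j_window: int = 40

    def validate(self, ref: ReferenceSet) -> None:
        if self.chain not in ("TRG", "TRD"):
            raise ValueError(f"chain must be TRG or TRD, got {self.chain}")
        if self.n_reads <= 0 or self.n_clonotypes <= 0:
            raise ValueError("n_reads and n_clonotypes must be positive")
        if not 0 <= self.error_rate <= 0.1:
            raise ValueError("error_rate must be in [0, 0.1]")
        if self.canonical_spike and self.chain != "TRG":
            raise ValueError("canonical_spike requires chain TRG")
        if not 0 <= self.canonical_spike <= 1:
            raise ValueError("canonical_spike must be in [0, 1]")
        for name, usage in (("v_usage", self.v_usage),
                            ("j_usage", self.j_usage)):
            if not usage:
                raise ValueError(f"{name} is empty")
            if abs(sum(usage.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} does not sum to 1")
            for sid in usage:
                seg = ref.get_segment(sid)  # raises on unknown id
                if seg.chain != self.chain:
                    raise ValueError(f"{sid} is not a {self.chain} segment")


def default_trg_usage(ref: ReferenceSet) -> tuple[dict, dict]:
    """Vγ9-biased V usage over functional TRGV and near-uniform J usage."""
    vs = [s.segment_id for s in ref.by_type("V", "TRG") if s.functional]
    v_usage = {v: 0.5 / (len(vs) - 1) for v in vs if v != "TRGV9"}
    v_usage["TRGV9"] = 0.5
    js = [s.segment_id for s in ref.by_type("J", "TRG")]
    j_usage = {j: 1.0 / len(js) for j in js}
    return v_usage, j_usage


@dataclass
class SimTruth:
    """Ground truth for one simulated read."""

    read_id: str
    v_id: str
    j_id: str
    d_id: Optional[str]
    v_trim: int
    j_trim: int
    d_trim5: int
    d_trim3: int
    n1_insert: str
    n2_insert: str
    junction_nt: str
    junction_aa: str
    in_frame: bool
    in_window: bool
    clonotype_index: int


@dataclass
class _Clonotype:
    v_id: str
    j_id: str
    d_id: Optional[str]
    v_trim: int
    j_trim: int
    d_trim5: int
    d_trim3: int
    n1: str
    n2: str
    read: str = ""          # error-free amplicon sequence
    junction_nt: str = ""
    junction_aa: str = ""
    in_frame: bool = False
    in_window: bool = False

    def key(self) -> tuple:
        return (self.v_id, self.j_id, self.junction_nt)


@dataclass
class SimResult:
    """Simulated reads (id, sequence) plus per-read ground truth."""

    reads: list[tuple[str, str]]
    truth: list[SimTruth]
    config: SimulationConfig

    def write_fastq(self, path: str | Path) -> None:
        qual = "?"  # Phred+33 Q30
        with open(path, "w") as fh:
            for read_id, seq in self.reads:
                fh.write(f"@{read_id}\n{seq}\n+\n{qual * len(seq)}\n")

    def write_truth(self, path: str | Path) -> None:
        cols = ("read_id\tv_call\td_call\tj_call\tjunction\tjunction_aa\t"
                "np1_length\tnp2_length\tv_trim\tj_trim\tclonotype_index\t"
                "in_window\n")
        with open(path, "w") as fh:
            fh.write(cols)
            for t in self.truth:
                fh.write("\t".join(map(str, (
                    t.read_id, t.v_id, t.d_id or "", t.j_id, t.junction_nt,
                    t.junction_aa, len(t.n1_insert), len(t.n2_insert),
                    t.v_trim, t.j_trim, t.clonotype_index,
                    str(t.in_window).lower()))) + "\n")


def _rand_nt(rng: np.random.Generator, n: int) -> str:
    if n == 0:
        return ""
    return rng.choice(BASES, size=n).tobytes().decode("ascii")


def _geometric0(rng: np.random.Generator, mean: float) -> int:
    """Geometric on {0,1,2,...} with the given mean."""
    if mean <= 0:
        return 0
    return int(rng.geometric(1.0 / (1.0 + mean))) - 1


def _finish_clonotype(ct: _Clonotype, ref: ReferenceSet,
                      config: SimulationConfig) -> _Clonotype:
    """Assemble the error-free amplicon read and the truth junction."""
    v = ref.get_segment(ct.v_id)
    j = ref.get_segment(ct.j_id)
    middle = ct.n1
    if ct.d_id is not None:
        d = ref.get_segment(ct.d_id).sequence
        d_part = d[ct.d_trim5:len(d) - ct.d_trim3] \
            if ct.d_trim5 + ct.d_trim3 < len(d) else ""
        middle = ct.n1 + d_part + ct.n2
    v_part = v.sequence[:len(v.sequence) - ct.v_trim]
    j_part = j.sequence[ct.j_trim:]
    ct.read = v_part[-config.v_window:] + middle + j_part[:config.j_window]

    cys, fw = v.cys_anchor, j.fw_anchor
    in_window = (cys is not None and fw is not None
                 and ct.v_trim <= len(v.sequence) - cys - 3
                 and ct.j_trim <= fw
                 and len(v.sequence) - cys <= config.v_window
                 and fw + 3 - ct.j_trim <= config.j_window)
    ct.in_window = in_window
    if in_window:
        ct.junction_nt = (v.sequence[cys:len(v.sequence) - ct.v_trim]
                          + middle + j.sequence[ct.j_trim:fw + 3])
        ct.in_frame = len(ct.junction_nt) % 3 == 0
        if ct.in_frame:
            ct.junction_aa = str(Seq(ct.junction_nt).translate())
    return ct


def _draw_clonotype(rng: np.random.Generator, ref: ReferenceSet,
                    config: SimulationConfig,
                    v_ids: list[str], v_p: np.ndarray,
                    j_ids: list[str], j_p: np.ndarray,
                    d_ids: list[str]) -> _Clonotype:
    v_id = v_ids[int(rng.choice(len(v_ids), p=v_p))]
    j_id = j_ids[int(rng.choice(len(j_ids), p=j_p))]
    d_id = None
    d_trim5 = d_trim3 = 0
    n2 = ""
    if config.chain == "TRD":
        d_id = d_ids[int(rng.integers(len(d_ids)))]
        d_trim5 = _geometric0(rng, config.trim_mean)
        d_trim3 = _geometric0(rng, config.trim_mean)
        n2 = _rand_nt(rng, int(rng.poisson(config.n_insert_mean)))
    ct = _Clonotype(
        v_id=v_id, j_id=j_id, d_id=d_id,
        v_trim=_geometric0(rng, config.trim_mean),
        j_trim=_geometric0(rng, config.trim_mean),
        d_trim5=d_trim5, d_trim3=d_trim3,
        n1=_rand_nt(rng, int(rng.poisson(config.n_insert_mean))),
        n2=n2)
    return _finish_clonotype(ct, ref, config)


def canonical_clonotype(ref: ReferenceSet,
                        config: Optional[SimulationConfig] = None
                        ) -> _Clonotype:
    """The germline-encoded canonical Vγ9-JγP clonotype (zero trim, zero
    N-addition); its CDR3 translates to ALWEVQELGKKIKV."""
    config = config or SimulationConfig()
    ct = _Clonotype(v_id=CANONICAL_V, j_id=CANONICAL_J, d_id=None,
                    v_trim=0, j_trim=0, d_trim5=0, d_trim3=0, n1="", n2="")
    return _finish_clonotype(ct, ref, config)


def simulate_repertoire(ref: ReferenceSet, config: SimulationConfig,
                        clonotypes: Optional[list[_Clonotype]] = None,
                        frequencies: Optional[np.ndarray] = None
                        ) -> SimResult:
    """Simulate one repertoire; identical seed + config give byte-identical
    output.  ``clonotypes``/``frequencies`` override the random draw (used
    by scenario builders)."""
    config.validate(ref)
    rng = np.random.default_rng(config.seed)
    v_ids = list(config.v_usage)
    v_p = np.array([config.v_usage[v] for v in v_ids])
    v_p = v_p / v_p.sum()
    j_ids = list(config.j_usage)
    j_p = np.array([config.j_usage[j] for j in j_ids])
    j_p = j_p / j_p.sum()
    d_ids = [s.segment_id for s in ref.by_type("D", "TRD")]

    if clonotypes is None:
        clonotypes = [_draw_clonotype(rng, ref, config, v_ids, v_p,
                                      j_ids, j_p, d_ids)
                      for _ in range(config.n_clonotypes)]
    if frequencies is None:
        frequencies = rng.dirichlet(
            np.full(len(clonotypes), config.clonotype_concentration))
    frequencies = np.asarray(frequencies, dtype=float)
    frequencies = frequencies / frequencies.sum()

    canon = canonical_clonotype(ref, config) \
        if config.canonical_spike > 0 else None

    reads: list[tuple[str, str]] = []
    truth: list[SimTruth] = []
    choices = rng.choice(len(clonotypes), size=config.n_reads, p=frequencies)
    spike = rng.random(config.n_reads) < config.canonical_spike \
        if canon is not None else np.zeros(config.n_reads, dtype=bool)
    for i in range(config.n_reads):
        if spike[i]:
            ct, ct_index = canon, -1
        else:
            ct_index = int(choices[i])
            ct = clonotypes[ct_index]
        seq = ct.read
        if config.error_rate > 0:
            arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
            hits = np.nonzero(rng.random(arr.size) < config.error_rate)[0]
            for pos in hits:
                alt = BASES[BASES != arr[pos]]
                arr[pos] = alt[int(rng.integers(3))]
            seq = arr.tobytes().decode("ascii")
        read_id = f"sim_{config.chain}_{config.seed}_{i:06d}"
        reads.append((read_id, seq))
        truth.append(SimTruth(
            read_id=read_id, v_id=ct.v_id, j_id=ct.j_id, d_id=ct.d_id,
            v_trim=ct.v_trim, j_trim=ct.j_trim,
            d_trim5=ct.d_trim5, d_trim3=ct.d_trim3,
            n1_insert=ct.n1, n2_insert=ct.n2,
            junction_nt=ct.junction_nt, junction_aa=ct.junction_aa,
            in_frame=ct.in_frame, in_window=ct.in_window,
            clonotype_index=ct_index))
    return SimResult(reads=reads, truth=truth, config=config)


def blood_tumor_scenario(ref: ReferenceSet, seed: int,
                         n_reads: int = 3000) -> dict[str, SimResult]:
    """Paired blood/tumor TRG samples plus an oligoclonal pair.

    blood:  canonical-spiked, JγP-heavy J usage (diverse, public-dominant).
    tumor:  Jγ2-heavy J usage, skewed clonotype frequencies, top clonotypes
            forced to non-canonical Vγ9-Jγ2 and disjoint from blood.
    oligo_blood / oligo_tumor: case-3-like — one clonotype at 96% of blood
            reads, clonotype sets forced disjoint, no sequencing error.
    """
    v_usage, _ = default_trg_usage(ref)
    jp_heavy = {"TRGJP": 0.60, "TRGJ1": 0.15, "TRGJ2": 0.15,
                "TRGJP1": 0.05, "TRGJP2": 0.05}
    j2_heavy = {"TRGJ2": 0.60, "TRGJP": 0.20, "TRGJ1": 0.10,
                "TRGJP1": 0.05, "TRGJP2": 0.05}

    blood_cfg = SimulationConfig(
        chain="TRG", n_reads=n_reads, v_usage=v_usage, j_usage=jp_heavy,
        n_clonotypes=200, clonotype_concentration=2.0,
        error_rate=0.002, canonical_spike=0.35, seed=seed * 4 + 0)
    blood = simulate_repertoire(ref, blood_cfg)
    blood_keys = {t.junction_nt for t in blood.truth}

    tumor_cfg = SimulationConfig(
        chain="TRG", n_reads=n_reads, v_usage=v_usage, j_usage=j2_heavy,
        n_clonotypes=80, clonotype_concentration=0.3,
        error_rate=0.002, canonical_spike=0.05, seed=seed * 4 + 1)
    tumor = _forced_dominant_run(ref, tumor_cfg, forbid=blood_keys,
                                 dominant_v=CANONICAL_V, dominant_j="TRGJ2",
                                 n_dominant=3)

    oligo_b_cfg = SimulationConfig(
        chain="TRG", n_reads=n_reads, v_usage=v_usage, j_usage=jp_heavy,
        n_clonotypes=5, error_rate=0.0, canonical_spike=0.0,
        n_insert_mean=6.0, seed=seed * 4 + 2)
    freqs_b = np.array([0.96, 0.01, 0.01, 0.01, 0.01])
    oligo_blood = _disjoint_run(ref, oligo_b_cfg, forbid=set(),
                                frequencies=freqs_b)
    oligo_t_cfg = replace(oligo_b_cfg, j_usage=j2_heavy, n_clonotypes=8,
                          seed=seed * 4 + 3)
    oligo_tumor = _disjoint_run(
        ref, oligo_t_cfg,
        forbid={t.junction_nt for t in oligo_blood.truth},
        frequencies=np.array([0.5, 0.2, 0.1, 0.05, 0.05, 0.05, 0.03, 0.02]))

    return {"blood": blood, "tumor": tumor,
            "oligo_blood": oligo_blood, "oligo_tumor": oligo_tumor}


def _draw_all(rng, ref, config):
    v_ids = list(config.v_usage)
    v_p = np.array([config.v_usage[v] for v in v_ids])
    v_p /= v_p.sum()
    j_ids = list(config.j_usage)
    j_p = np.array([config.j_usage[j] for j in j_ids])
    j_p /= j_p.sum()
    d_ids = [s.segment_id for s in ref.by_type("D", "TRD")]
    return [_draw_clonotype(rng, ref, config, v_ids, v_p, j_ids, j_p, d_ids)
            for _ in range(config.n_clonotypes)]


def _disjoint_run(ref, config, forbid: set[str],
                  frequencies: Optional[np.ndarray] = None) -> SimResult:
    """Simulate with clonotype junctions forced outside ``forbid`` and
    unique within the run (redraws N-inserts until disjoint)."""
    config.validate(ref)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 911]))
    cts = _draw_all(rng, ref, config)
    seen = set(forbid)
    for ct in cts:
        while (not ct.in_window) or ct.junction_nt in seen:
            extra = 1 + int(rng.poisson(config.n_insert_mean))
            ct.n1 = _rand_nt(rng, extra)
            ct.v_trim = _geometric0(rng, config.trim_mean)
            ct.j_trim = _geometric0(rng, config.trim_mean)
            _finish_clonotype(ct, ref, config)
        seen.add(ct.junction_nt)
    return simulate_repertoire(ref, config, clonotypes=cts,
                               frequencies=frequencies)


def _forced_dominant_run(ref, config, forbid: set[str], dominant_v: str,
                         dominant_j: str, n_dominant: int) -> SimResult:
    """Simulate with the highest-frequency clonotypes forced to a given
    V-J pair, with non-empty N regions, disjoint from ``forbid``."""
    config.validate(ref)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 417]))
    cts = _draw_all(rng, ref, config)
    freqs = rng.dirichlet(
        np.full(len(cts), config.clonotype_concentration))
    top = np.argsort(freqs)[::-1][:n_dominant]
    seen = set(forbid)
    for ct in cts:
        seen.add(ct.junction_nt)
    for idx in top:
        ct = cts[idx]
        ct.v_id, ct.j_id = dominant_v, dominant_j
        seen.discard(ct.junction_nt)
        ct.junction_nt = ""
        ct.in_window = False  # force regeneration with the new V-J pair
        while (not ct.in_window) or (not ct.n1) or ct.junction_nt in seen:
            ct.n1 = _rand_nt(rng, 2 + int(rng.poisson(config.n_insert_mean)))
            ct.v_trim = _geometric0(rng, config.trim_mean)
            ct.j_trim = _geometric0(rng, config.trim_mean)
            _finish_clonotype(ct, ref, config)
        seen.add(ct.junction_nt)
    return simulate_repertoire(ref, config, clonotypes=cts,
                               frequencies=freqs)


def simulate_bulk_reads(ref: ReferenceSet, n_reads: int,
                        gene_fractions: dict[str, float],
                        read_length: int = 75, error_rate: float = 0.0,
                        seed: int = 0) -> tuple[list[tuple[str, str]],
                                                list[str]]:
    """Bulk RNA-seq stand-in: reads are random substrings of constant-gene
    sequences (per ``gene_fractions``; remainder is random background).
    Returns (reads, per-read source labels; background = "")."""
    rng = np.random.default_rng(seed)
    total = sum(gene_fractions.values())
    if total > 1 + 1e-9:
        raise ValueError("gene fractions sum to more than 1")
    labels = list(gene_fractions) + [""]
    probs = np.array([gene_fractions[g] for g in gene_fractions]
                     + [max(0.0, 1.0 - total)])
    probs /= probs.sum()
    picks = rng.choice(len(labels), size=n_reads, p=probs)
    reads, sources = [], []
    for i, k in enumerate(picks):
        label = labels[int(k)]
        if label:
            seq_full = ref.get_segment(label).sequence
            start = int(rng.integers(0, max(1, len(seq_full) - read_length)))
            seq = seq_full[start:start + read_length]
        else:
            seq = _rand_nt(rng, read_length)
        if error_rate > 0:
            arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
            for pos in np.nonzero(rng.random(arr.size) < error_rate)[0]:
                alt = BASES[BASES != arr[pos]]
                arr[pos] = alt[int(rng.integers(3))]
            seq = arr.tobytes().decode("ascii")
        reads.append((f"bulk_{seed}_{i:06d}", seq))
        sources.append(label)
    return reads, sources
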