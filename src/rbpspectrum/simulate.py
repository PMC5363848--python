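"""Synthetic binding-cluster sequences and toy genome bundles.

Real PAR-CLIP clusters for these two proteins are short 3'UTR fragments:
U-rich for HuR (lengths 19-243 nt, mean 56) and AU-rich for TTP (21-172 nt,
mean 26), with canonical motifs (poly-U tracts; the AUUUAUUUA nonamer) and a
large fraction of co-bound sites.  This module generates labeled sequence
sets and complete toy genome bundles (genome FASTA + 3'UTR annotation + two
cluster BED files + a truth table) with exactly that statistical structure,
so every pipeline stage can be exercised end to end without external data.

Cluster lengths follow a shifted geometric law truncated to [min, max] and
calibrated to the target mean — matching the right-skew of real cluster
length distributions (mean far below max).  Motifs are embedded
independently per sequence at a uniform offset, overwriting background;
every generator is a pure function of its spec including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .seqdata import (
    GenomicInterval,
    SequenceRecord,
    TranscriptAnnotation,
    write_bed,
    write_labeled_fasta,
)

__all__ = [
    "GeneratorSpec",
    "ToyBundle",
    "HUR_LENGTH_MODEL",
    "TTP_LENGTH_MODEL",
    "UTR_COMPOSITION",
    "sample_sequences",
    "make_hur_like",
    "make_ttp_like",
    "make_background",
    "make_toy_bundle",
]

#: (mean, min, max) cluster length presets for the two proteins.
HUR_LENGTH_MODEL = (56, 19, 243)
TTP_LENGTH_MODEL = (26, 21, 172)

#: Background base probabilities (A, C, G, U) for 3'UTR-like sequence:
#: mildly AU-rich, as human 3'UTRs are.
UTR_COMPOSITION = {"A": 0.28, "C": 0.18, "G": 0.18, "U": 0.36}

HUR_COMPOSITION = {"A": 0.15, "C": 0.10, "G": 0.10, "U": 0.65}
TTP_COMPOSITION = {"A": 0.35, "C": 0.08, "G": 0.07, "U": 0.50}
HUR_MOTIFS = (("UUUUUUUUU", 0.4), ("UUUAUUUUU", 0.4), ("CUUUUUUUU", 0.4))
TTP_MOTIFS = (("AUUUAUUUA", 0.4), ("UAUUUAUUU", 0.4), ("UUAUUUAUU", 0.4))


@dataclass
class GeneratorSpec:
    """Everything needed to sample one labeled sequence set."""

    n: int
    length_model: tuple  # (mean, min, max)
    composition: dict  # base -> probability, sums to 1
    motifs: tuple = ()  # ((motif, embedding probability), ...)
    seed: int = 0
    label: str = "positive"
    domain: str | None = None
    id_prefix: str = "syn"

    def __post_init__(self):
        mean, lo, hi = self.length_model
        if not (lo <= mean <= hi):
            raise ValueError(f"need min <= mean <= max, got {self.length_model}")
        total = sum(self.composition.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"composition sums to {total}, not 1")
        for motif, p in self.motifs:
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"embedding probability {p} outside [0,1]")
            if len(motif) > lo:
                raise ValueError(
                    f"motif {motif!r} (len {len(motif)}) longer than "
                    f"minimum length {lo}"
                )


def _truncated_geometric_pmf(mean: float, lo: int, hi: int) -> np.ndarray:
    """pmf over lengths lo..hi: P(L = lo + j) ~ q^j, calibrated to the mean.

    The decay rate q is found by bisection so the truncated mean hits the
    target (up to the degenerate ends of the support).
    """
    support = np.arange(lo, hi + 1)
    if lo == hi:
        return np.ones(1)
    j = np.arange(len(support), dtype=float)

    def weights(q: float) -> np.ndarray:
        # geometric weights computed in log space to stay finite for q > 1
        logw = j * np.log(q)
        w = np.exp(logw - logw.max())
        return w / w.sum()

    def trunc_mean(q: float) -> float:
        return float((weights(q) * support).sum())

    # truncated mean is increasing in q: q < 1 skews toward lo, q > 1 toward hi
    lo_q, hi_q = 1e-9, 1e9
    for _ in range(200):
        q = (lo_q + hi_q) / 2
        if trunc_mean(q) < mean:
            lo_q = q
        else:
            hi_q = q
    return weights((lo_q + hi_q) / 2)


def _random_bases(rng: np.random.Generator, n: int, composition: dict) -> np.ndarray:
    bases = np.array(list(composition.keys()))
    probs = np.array(list(composition.values()), dtype=float)
    probs /= probs.sum()
    return rng.choice(bases, size=n, p=probs)


def sample_sequences(spec: GeneratorSpec) -> list[SequenceRecord]:
    """Draw ``spec.n`` labeled records under the generator law."""
    rng = np.random.default_rng(spec.seed)
    mean, lo, hi = spec.length_model
    pmf = _truncated_geometric_pmf(mean, lo, hi)
    lengths = rng.choice(np.arange(lo, hi + 1), size=spec.n, p=pmf)
    records = []
    for i, length in enumerate(lengths):
        chars = _random_bases(rng, int(length), spec.composition)
        embedded = []
        for motif, p in spec.motifs:
            if rng.random() < p:
                offset = int(rng.integers(0, length - len(motif) + 1))
                chars[offset : offset + len(motif)] = list(motif)
                embedded.append(motif)
        records.append(
            SequenceRecord(
                f"{spec.id_prefix}_{i}",
                "".join(chars),
                spec.label,
                spec.domain,
            )
        )
    return records


def make_hur_like(n: int, seed: int = 0, label: str = "positive") -> list[SequenceRecord]:
    """U-rich cluster sequences with HuR-like lengths and poly-U motifs."""
    return sample_sequences(
        GeneratorSpec(
            n=n,
            length_model=HUR_LENGTH_MODEL,
            composition=HUR_COMPOSITION,
            motifs=HUR_MOTIFS,
            seed=seed,
            label=label,
            domain="HuR",
            id_prefix="hur",
        )
    )


def make_ttp_like(n: int, seed: int = 0, label: str = "positive") -> list[SequenceRecord]:
    """AU-rich cluster sequences with TTP-like lengths and AUUUA-repeat motifs."""
    return sample_sequences(
        GeneratorSpec(
            n=n,
            length_model=TTP_LENGTH_MODEL,
            composition=TTP_COMPOSITION,
            motifs=TTP_MOTIFS,
            seed=seed,
            label=label,
            domain="TTP",
            id_prefix="ttp",
        )
    )


def make_background(
    n: int,
    seed: int = 0,
    length_model: tuple = HUR_LENGTH_MODEL,
    domain: str | None = None,
) -> list[SequenceRecord]:
    """Motif-free 3'UTR-like background sequences, labeled negative."""
    return sample_sequences(
        GeneratorSpec(
            n=n,
            length_model=length_model,
            composition=UTR_COMPOSITION,
            seed=seed,
            label="negative",
            domain=domain,
            id_prefix="bg",
        )
    )


@dataclass
class ToyBundle:
    """A self-consistent toy genome with planted binding clusters.

    ``truth`` records, per interval, the owning domain, embedded motifs and
    whether the site is shared (co-bound) — the ground truth tests assert
    against.
    """

    genome: dict
    utr_annotation: TranscriptAnnotation
    hur_intervals: list
    ttp_intervals: list
    truth: pd.DataFrame
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def write(self, outdir) -> None:
        """Write genome FASTA, annotation/cluster BEDs and the truth table."""
        import os

        os.makedirs(outdir, exist_ok=True)
        with open(os.path.join(outdir, "genome.fa"), "w") as fh:
            for chrom, seq in self.genome.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")
        write_bed(self.utr_annotation.intervals, os.path.join(outdir, "utr.bed"))
        write_bed(self.hur_intervals, os.path.join(outdir, "hur.bed"))
        write_bed(self.ttp_intervals, os.path.join(outdir, "ttp.bed"))
        self.truth.to_csv(os.path.join(outdir, "truth.tsv"), sep="\t", index=False)


def _embed_cluster(
    genome_chars: np.ndarray,
    rng: np.random.Generator,
    start: int,
    length: int,
    composition: dict,
    motifs,
) -> list[str]:
    """Overwrite genome DNA at [start, start+length) with a cluster sequence."""
    chars = _random_bases(rng, length, composition)
    embedded = []
    for motif, p in motifs:
        if length >= len(motif) and rng.random() < p:
            off = int(rng.integers(0, length - len(motif) + 1))
            chars[off : off + len(motif)] = list(motif)
            embedded.append(motif)
    genome_chars[start : start + length] = [c.replace("U", "T") for c in chars]
    return embedded


def make_toy_bundle(
    n_hur: int,
    n_ttp: int,
    shared_fraction: float,
    genome_size: int | None = None,
    seed: int = 0,
) -> ToyBundle:
    """Build a toy genome with planted HuR and TTP clusters and free 3'UTRs.

    A fraction ``shared_fraction`` of the TTP clusters is placed overlapping
    a distinct HuR cluster (co-bound sites); the rest are placed apart.
    Every cluster sits inside a 3'UTR transcript; additional cluster-free
    transcripts are appended for control sampling.  Deterministic per seed.
    """
    if not (0.0 <= shared_fraction <= 1.0):
        raise ValueError("shared_fraction must be in [0, 1]")
    n_shared = int(round(shared_fraction * n_ttp))
    if n_shared > n_hur:
        raise ValueError(
            f"{n_shared} shared TTP clusters requested but only {n_hur} HuR hosts"
        )
    rng = np.random.default_rng(seed)

    hur_pmf = _truncated_geometric_pmf(*_reorder(HUR_LENGTH_MODEL))
    ttp_pmf = _truncated_geometric_pmf(*_reorder(TTP_LENGTH_MODEL))
    hur_support = np.arange(HUR_LENGTH_MODEL[1], HUR_LENGTH_MODEL[2] + 1)
    ttp_support = np.arange(TTP_LENGTH_MODEL[1], TTP_LENGTH_MODEL[2] + 1)
    hur_lengths = rng.choice(hur_support, size=n_hur, p=hur_pmf)
    ttp_lengths = rng.choice(ttp_support, size=n_ttp, p=ttp_pmf)

    n_free_tx = max(20, (n_hur + n_ttp) // 4)
    free_tx_len = 1500
    flank, gap = 150, 200
    required = (
        int(hur_lengths.sum() + ttp_lengths.sum())
        + (n_hur + n_ttp) * (2 * flank + gap)
        + n_free_tx * (free_tx_len + gap)
        + 1000
    )
    if genome_size is None:
        genome_size = required
    elif genome_size < required:
        raise ValueError(
            f"genome_size {genome_size} too small; need >= {required}"
        )

    chrom = "chr1"
    genome_chars = _random_bases(rng, genome_size, UTR_COMPOSITION)
    genome_chars = np.char.replace(genome_chars, "U", "T")

    hur_intervals: list[GenomicInterval] = []
    ttp_intervals: list[GenomicInterval] = []
    transcripts: list[GenomicInterval] = []
    truth_rows = []
    cursor = 100

    shared_hosts = set(rng.choice(n_hur, size=n_shared, replace=False).tolist())
    ttp_shared_lengths = ttp_lengths[:n_shared]
    ttp_exclusive_lengths = ttp_lengths[n_shared:]

    shared_iter = iter(ttp_shared_lengths)
    for i in range(n_hur):
        h_len = int(hur_lengths[i])
        tx_start = cursor
        start = cursor + flank
        motifs = _embed_cluster(
            genome_chars, rng, start, h_len, HUR_COMPOSITION, HUR_MOTIFS
        )
        hur_iv = GenomicInterval(chrom, start, start + h_len, f"hur_{i}", "+")
        hur_intervals.append(hur_iv)
        shared = i in shared_hosts
        truth_rows.append(
            {"name": hur_iv.name, "domain": "HuR", "motifs": ",".join(motifs),
             "shared": shared}
        )
        cluster_end = start + h_len
        if shared:
            t_len = int(next(shared_iter))
            # overlap the tail of the HuR cluster by >=1 bp
            max_back = min(t_len - 1, h_len - 1)
            back = int(rng.integers(1, max_back + 1))
            t_start = cluster_end - back
            t_motifs = _embed_cluster(
                genome_chars, rng, t_start, t_len, TTP_COMPOSITION, TTP_MOTIFS
            )
            ttp_iv = GenomicInterval(
                chrom, t_start, t_start + t_len, f"ttp_s{i}", "+"
            )
            ttp_intervals.append(ttp_iv)
            truth_rows.append(
                {"name": ttp_iv.name, "domain": "TTP",
                 "motifs": ",".join(t_motifs), "shared": True}
            )
            cluster_end = max(cluster_end, t_start + t_len)
        tx_end = cluster_end + flank
        transcripts.append(
            GenomicInterval(chrom, tx_start, tx_end, f"tx_hur_{i}", "+")
        )
        cursor = tx_end + gap

    for j, t_len in enumerate(ttp_exclusive_lengths):
        t_len = int(t_len)
        tx_start = cursor
        start = cursor + flank
        motifs = _embed_cluster(
            genome_chars, rng, start, t_len, TTP_COMPOSITION, TTP_MOTIFS
        )
        ttp_iv = GenomicInterval(chrom, start, start + t_len, f"ttp_{j}", "+")
        ttp_intervals.append(ttp_iv)
        truth_rows.append(
            {"name": ttp_iv.name, "domain": "TTP", "motifs": ",".join(motifs),
             "shared": False}
        )
        tx_end = start + t_len + flank
        transcripts.append(
            GenomicInterval(chrom, tx_start, tx_end, f"tx_ttp_{j}", "+")
        )
        cursor = tx_end + gap

    for m in range(n_free_tx):
        transcripts.append(
            GenomicInterval(chrom, cursor, cursor + free_tx_len, f"tx_free_{m}", "+")
        )
        cursor += free_tx_len + gap

    if cursor > genome_size:
        raise ValueError("genome too small for requested intervals")

    genome = {chrom: "".join(genome_chars.tolist())}
    return ToyBundle(
        genome=genome,
        utr_annotation=TranscriptAnnotation(transcripts),
        hur_intervals=hur_intervals,
        ttp_intervals=ttp_intervals,
        truth=pd.DataFrame(truth_rows),
        seed=seed,
    )


def _reorder(length_model: tuple) -> tuple:
    mean, lo, hi = length_model
    return mean, lo, hi


def write_sequences(records, path) -> None:
    """Convenience: serialize generated records as labeled FASTA."""
    write_labeled_fasta(records, path)
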