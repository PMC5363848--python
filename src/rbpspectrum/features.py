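"""Explicit feature maps for the k-spectrum kernel and its extensions.

The spectrum feature map of a sequence is the vector of counts of every
length-k substring, here taken as the union over all k in [k1, k2].  On top
of that sit seven engineered composition features (base frequencies, run
statistics and AU-dimer density, each normalized by sequence length) and the
feature-augmentation construction used for domain adaptation: every feature
is duplicated into a shared copy and a domain-specific copy ("HuR_..." /
"TTP_..."), so a single linear model can learn which effects transfer across
domains.

All vectors are sparse name->value mappings; the linear kernel is a plain
dot product over shared names, which makes the kernel identities of the
augmented map easy to state and test: same-domain inner products double,
cross-domain inner products are unchanged.
"""

from __future__ import annotations

import math
import re
from collections import Counter
from dataclasses import dataclass, field

__all__ = [
    "RNA_ALPHABET",
    "ENGINEERED_NAMES",
    "DOMAINS",
    "SpectrumProfile",
    "FeatureVector",
    "spectrum_profile",
    "engineered_vector",
    "combine",
    "augment",
    "dot",
    "build_vectors",
    "write_vectors_tsv",
    "read_vectors_tsv",
]

RNA_ALPHABET = "ACGU"
ENGINEERED_NAMES = (
    "aCount",
    "uCount",
    "gCount",
    "cCount",
    "aRepeatedCount",
    "uRepeatedCount",
    "auCount",
)
DOMAINS = ("HuR", "TTP")

_AU = frozenset("AU")


@dataclass
class SpectrumProfile:
    """Sparse k-mer -> count map over all k-mer lengths in [k_min, k_max]."""

    counts: dict[str, int]
    k_min: int
    k_max: int


@dataclass
class FeatureVector:
    """Sparse named feature vector with block provenance.

    ``provenance`` records which blocks are present: any of ``"spectrum"``,
    ``"engineered"``, ``"augmented"``.
    """

    entries: dict[str, float]
    provenance: frozenset = field(default_factory=frozenset)


def spectrum_profile(seq: str, k1: int, k2: int) -> SpectrumProfile:
    """Count every overlapping window of each length k in [k1, k2].

    Windows containing a character outside {A,C,G,U} are skipped; sequences
    shorter than k contribute nothing for that k.
    """
    if k1 < 1 or k1 > k2:
        raise ValueError(f"require 1 <= k1 <= k2, got k1={k1}, k2={k2}")
    if not seq:
        raise ValueError("empty sequence")
    n = len(seq)
    # prefix count of invalid characters: window [i, i+k) is clean iff
    # bad[i+k] - bad[i] == 0
    bad = [0] * (n + 1)
    for i, ch in enumerate(seq):
        bad[i + 1] = bad[i] + (ch not in RNA_ALPHABET)
    counts: Counter[str] = Counter()
    for k in range(k1, k2 + 1):
        for i in range(n - k + 1):
            if bad[i + k] - bad[i] == 0:
                counts[seq[i : i + k]] += 1
    return SpectrumProfile(dict(counts), k1, k2)


_RUN_RE = {base: re.compile(f"{base}{{2,}}") for base in "AU"}


def engineered_vector(seq: str, run_mode: str = "runs") -> dict[str, float]:
    """The seven composition features, each normalized by sequence length.

    aCount/uCount/gCount/cCount are base frequencies; aRepeatedCount and
    uRepeatedCount summarize homopolymer runs of length >= 2 (``run_mode``
    "runs" counts maximal runs, "bases" counts the bases inside them);
    auCount counts overlapping AU-rich dimers (AA, AU, UA, UU).
    """
    if not seq:
        raise ValueError("empty sequence")
    if run_mode not in ("runs", "bases"):
        raise ValueError(f"unknown run_mode {run_mode!r}")
    L = len(seq)
    vec = {
        "aCount": seq.count("A") / L,
        "uCount": seq.count("U") / L,
        "gCount": seq.count("G") / L,
        "cCount": seq.count("C") / L,
    }
    for base, key in (("A", "aRepeatedCount"), ("U", "uRepeatedCount")):
        runs = _RUN_RE[base].findall(seq)
        stat = len(runs) if run_mode == "runs" else sum(len(r) for r in runs)
        vec[key] = stat / L
    vec["auCount"] = (
        sum(1 for i in range(L - 1) if seq[i] in _AU and seq[i + 1] in _AU) / L
    )
    return vec


def combine(
    spectrum: SpectrumProfile,
    engineered: dict[str, float] | None = None,
    normalize: bool = False,
) -> FeatureVector:
    """Concatenate spectrum counts with (optionally) engineered features.

    No standardization is applied: engineered features are fractions in
    [0, 1] and spectrum entries are raw integer counts.  ``normalize``
    rescales the whole vector to unit L2 norm (cosine kernel).
    """
    entries: dict[str, float] = dict(spectrum.counts)
    provenance = {"spectrum"}
    if engineered is not None:
        for name, value in engineered.items():
            if name in entries:
                raise ValueError(f"feature name collision: {name!r}")
            entries[name] = value
        provenance.add("engineered")
    if normalize and entries:
        norm = math.sqrt(sum(v * v for v in entries.values()))
        if norm > 0:
            entries = {k: v / norm for k, v in entries.items()}
    return FeatureVector(entries, frozenset(provenance))


def augment(vec: FeatureVector, domain: str) -> FeatureVector:
    """Feature augmentation for domain adaptation.

    Every entry appears twice: under its original (shared) name and under
    ``"<domain>_<name>"``.  Copies for the other domain are implicitly zero,
    which yields the kernel identities dot(aug_d(x), aug_d(y)) = 2 dot(x, y)
    and dot(aug_d(x), aug_e(y)) = dot(x, y) for d != e.
    """
    if domain not in DOMAINS:
        raise ValueError(f"unknown domain {domain!r}; expected one of {DOMAINS}")
    entries = dict(vec.entries)
    for name, value in vec.entries.items():
        entries[f"{domain}_{name}"] = value
    return FeatureVector(entries, vec.provenance | {"augmented"})


def dot(u: FeatureVector, v: FeatureVector) -> float:
    """Linear kernel: sum over shared names of u[name] * v[name]."""
    a, b = u.entries, v.entries
    if len(b) < len(a):
        a, b = b, a
    return sum(value * b[name] for name, value in a.items() if name in b)


def build_vectors(
    records,
    k1: int,
    k2: int,
    engineered: bool = False,
    augment_by_domain: bool = False,
    restrict: set[str] | None = None,
    normalize: bool = False,
) -> list[FeatureVector]:
    """Feature vectors for a list of SequenceRecords under one parameter set.

    ``restrict`` keeps only the named features (applied before augmentation,
    as in the combined-model construction).  ``augment_by_domain`` applies
    :func:`augment` using each record's own domain tag.
    """
    vectors = []
    for rec in records:
        profile = spectrum_profile(rec.seq, k1, k2)
        eng = engineered_vector(rec.seq) if engineered else None
        vec = combine(profile, eng, normalize=normalize)
        if restrict is not None:
            vec = FeatureVector(
                {k: v for k, v in vec.entries.items() if k in restrict},
                vec.provenance,
            )
        if augment_by_domain:
            if rec.domain is None:
                raise ValueError(f"record {rec.id!r} lacks a domain tag")
            vec = augment(vec, rec.domain)
        vectors.append(vec)
    return vectors


def write_vectors_tsv(ids, vectors, path) -> None:
    """Sparse TSV serialization: record_id <TAB> feature_name <TAB> value."""
    with open(path, "w") as fh:
        for rec_id, vec in zip(ids, vectors):
            for name, value in sorted(vec.entries.items()):
                fh.write(f"{rec_id}\t{name}\t{value:.10g}\n")


def read_vectors_tsv(path) -> dict[str, FeatureVector]:
    out: dict[str, dict[str, float]] = {}
    with open(path) as fh:
        for line in fh:
            rec_id, name, value = line.rstrip("\n").split("\t")
            out.setdefault(rec_id, {})[name] = float(value)
    return {rec_id: FeatureVector(entries) for rec_id, entries in out.items()}
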