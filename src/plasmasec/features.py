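"""The 470-dimensional sequence feature encoding for secretory-protein prediction.

A protein is described by four concatenated blocks, in fixed order:

====== ====== ==========================================================
block  size   content
====== ====== ==========================================================
RAAC   20     relative amino-acid composition against a background
SS     39     secondary-structure content and super-secondary motifs
EC     400    evolutionary conservation: logistic-squashed PSSM sums
PP     11     physicochemical property class fractions
====== ====== ==========================================================

RAAC quantifies how much each residue type is enriched or depleted
relative to a reference composition (by default a Swiss-Prot-like
table): ``(f_a - bg_a) / bg_a``.  Secretory plasma proteins are known to
be enriched in threonine and cysteine and depleted in lysine, glutamine
and arginine, which is exactly the signal this block carries.

SS summarises a three-state (helix H, strand E, coil C) secondary
structure: three state-content values plus, for each of the twelve
ordered run-triplet motifs XYZ with X != Y and Y != Z (e.g. CHC — a coil
run, a helix run, a coil run), the fraction of residues covered by the
motif, the motif's share of all motif occurrences, and its mean length
relative to the sequence.

EC sums the PSSM log-odds scores per (observed residue type i, target
type j) pair — ``S_ij = sum over positions carrying residue i of
pssm[pos, j]`` — and squashes with a length-normalised logistic,
``1 / (1 + exp(-S_ij / L))``, making the 400 values independent of
sequence length.

PP averages eleven binary residue-class memberships (aliphatic, sulfur,
aromatic, ...) over the sequence, i.e. each value is the fraction of
residues in that class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Optional, Sequence

import numpy as np

from .io_formats import AA_ORDER, PSSMProfile, ProteinRecord, SSAnnotation

# ---------------------------------------------------------------------------
# Reference tables
# ---------------------------------------------------------------------------

# Swiss-Prot-like background amino-acid frequencies (fractions; renormalised
# below).  Overridable wherever a background is accepted.
SWISSPROT_BACKGROUND: dict[str, float] = {
    "A": 0.0825, "R": 0.0553, "N": 0.0406, "D": 0.0546, "C": 0.0138,
    "Q": 0.0393, "E": 0.0672, "G": 0.0707, "H": 0.0227, "I": 0.0591,
    "L": 0.0965, "K": 0.0580, "M": 0.0241, "F": 0.0386, "P": 0.0474,
    "S": 0.0664, "T": 0.0535, "W": 0.0110, "Y": 0.0292, "V": 0.0686,
}

# Eleven residue classes; the per-protein feature is the class fraction.
PROPERTY_CLASSES: dict[str, frozenset[str]] = {
    "aliphatic": frozenset("AGILPV"),
    "sulfur": frozenset("CM"),
    "aromatic": frozenset("FWYH"),
    "hydrophobic": frozenset("ACFILMVW"),
    "charge": frozenset("DEKRH"),
    "polar": frozenset("DEHKNQRSTY"),
    "positive": frozenset("KRH"),
    "acidic": frozenset("DE"),
    "small": frozenset("ACDGNPSTV"),
    "tiny": frozenset("ACGST"),
    "hydroxylic": frozenset("STY"),
}
PROPERTY_NAMES = list(PROPERTY_CLASSES)

# The 12 ordered run-triplet motifs XYZ over {C,E,H} with X != Y, Y != Z,
# in lexicographic order.  The six prevalent ones in secretory proteins
# (CHC, HCH, ECH, HCE, ECE, CEC) are a subset.
SS_MOTIFS: list[str] = [
    "".join(m)
    for m in product("CEH", repeat=3)
    if m[0] != m[1] and m[1] != m[2]
]

_AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}


@dataclass(frozen=True)
class BackgroundComposition:
    """Reference amino-acid frequencies used as the RAAC denominator."""

    freq: dict[str, float]

    def __post_init__(self) -> None:
        if set(self.freq) != set(AA_ORDER):
            raise ValueError("background must cover exactly the 20 amino acids")
        total = sum(self.freq.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"background frequencies sum to {total}, not 1")
        if any(v <= 0 for v in self.freq.values()):
            raise ValueError("background frequencies must all be positive")

    def as_vector(self) -> np.ndarray:
        return np.array([self.freq[a] for a in AA_ORDER])


def default_background() -> BackgroundComposition:
    total = sum(SWISSPROT_BACKGROUND.values())
    return BackgroundComposition({a: v / total for a, v in SWISSPROT_BACKGROUND.items()})


@dataclass(frozen=True)
class PropertyScaleSet:
    """Eleven named residue classes with [0, 1] membership per amino acid."""

    classes: dict[str, dict[str, float]]

    def __post_init__(self) -> None:
        if len(self.classes) != 11:
            raise ValueError("a property scale set must define 11 classes")
        for name, members in self.classes.items():
            if set(members) != set(AA_ORDER):
                raise ValueError(f"class {name!r} must assign a value to all 20 residues")
            if any(not 0 <= v <= 1 for v in members.values()):
                raise ValueError(f"class {name!r} has membership outside [0, 1]")


def load_background(path) -> BackgroundComposition:
    """Read a background composition from JSON: {"A": 0.0825, ...}.

    Frequencies are renormalised to sum to 1.
    """
    import json

    with open(path) as fh:
        raw = json.load(fh)
    total = sum(raw.values())
    return BackgroundComposition({a: v / total for a, v in raw.items()})


def load_property_scales(path) -> PropertyScaleSet:
    """Read property scales from JSON: {"aliphatic": {"A": 1, ...}, ...}.

    Classes may list memberships sparsely; absent residues default to 0.
    """
    import json

    with open(path) as fh:
        raw = json.load(fh)
    return PropertyScaleSet(
        {name: {a: float(members.get(a, 0.0)) for a in AA_ORDER}
         for name, members in raw.items()}
    )


def default_property_scales() -> PropertyScaleSet:
    return PropertyScaleSet(
        {
            name: {a: float(a in members) for a in AA_ORDER}
            for name, members in PROPERTY_CLASSES.items()
        }
    )


@dataclass(frozen=True)
class SSRun:
    """A maximal run of one secondary-structure state."""

    state: str
    start: int
    length: int


@dataclass
class FeatureVector:
    """The full 470-value encoding of one protein."""

    protein_id: str
    values: np.ndarray
    schema: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (470,):
            raise ValueError(f"{self.protein_id}: expected 470 values, got {self.values.shape}")
        if len(self.schema) != 470:
            raise ValueError("schema must have 470 names")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"{self.protein_id}: non-finite feature values")


@dataclass
class GroupRAACReport:
    """Dataset-level composition comparison with bootstrap significance."""

    relative_difference: dict[str, float]
    p_value: dict[str, float]
    n_boot: int
    seed: int


def feature_schema() -> list[str]:
    """Ordered names of all 470 features: RAAC(20) | SS(39) | EC(400) | PP(11)."""
    names = [f"RAAC_{a}" for a in AA_ORDER]
    names += [f"SS_content_{s}" for s in "CHE"]
    for m in SS_MOTIFS:
        names += [f"SS_{m}_resfrac", f"SS_{m}_motiffrac", f"SS_{m}_meanlen"]
    names += [f"EC_{a}_{b}" for a in AA_ORDER for b in AA_ORDER]
    names += [f"PP_{p}" for p in PROPERTY_NAMES]
    assert len(names) == 470
    return names


FEATURE_BLOCKS = {"RAAC": (0, 20), "SS": (20, 59), "EC": (59, 459), "PP": (459, 470)}


# ---------------------------------------------------------------------------
# Composition (RAAC block)
# ---------------------------------------------------------------------------

def composition(seq: str) -> np.ndarray:
    """Amino-acid composition as 20 fractions in PSI-BLAST order.

    X positions are excluded from the denominator; a sequence of only X
    has no defined composition and raises.
    """
    counts = np.zeros(20)
    for ch in seq:
        idx = _AA_INDEX.get(ch)
        if idx is not None:
            counts[idx] += 1
    total = counts.sum()
    if total == 0:
        raise ValueError("sequence has no canonical residues; composition undefined")
    return counts / total


def relative_composition(comp: np.ndarray, background: BackgroundComposition) -> np.ndarray:
    """Relative difference (comp - bg) / bg per residue type."""
    bg = background.as_vector()
    if np.any(bg <= 0):
        raise ValueError("background frequencies must be positive")
    return (np.asarray(comp, dtype=float) - bg) / bg


def _pooled_composition(seqs: Sequence[str]) -> np.ndarray:
    counts = np.zeros(20)
    for s in seqs:
        for ch in s:
            idx = _AA_INDEX.get(ch)
            if idx is not None:
                counts[idx] += 1
    total = counts.sum()
    if total == 0:
        raise ValueError("no canonical residues in sequence set")
    return counts / total


def group_raac(
    sample: Sequence[str],
    background: Sequence[str],
    n_boot: int = 10_000,
    seed: int = 0,
) -> GroupRAACReport:
    """Relative composition of a sequence set against a background set.

    The relative difference is computed on pooled residue counts.  The
    two-sided p-value per residue type comes from a pooled bootstrap:
    sequences from both sets are pooled, resampled with replacement into
    sets of the original sizes, and the null relative differences are
    compared against the observed ones.
    """
    import warnings

    if not sample or not background:
        raise ValueError("sample and background sets must be non-empty")
    if n_boot < 100:
        warnings.warn("n_boot < 100 gives unstable bootstrap p-values")
    samp = _pooled_composition(sample)
    bg = _pooled_composition(background)
    if np.any(bg == 0):
        # Absent residue types in the background make the ratio undefined;
        # substitute a half-count pseudo-frequency for those types only.
        total_bg = sum(len(s) for s in background)
        bg = np.where(bg == 0, 0.5 / total_bg, bg)
    observed = (samp - bg) / bg

    rng = np.random.default_rng(seed)
    pool = list(sample) + list(background)
    n_s, n_b = len(sample), len(background)
    exceed = np.zeros(20)
    for _ in range(n_boot):
        idx = rng.integers(0, len(pool), size=n_s + n_b)
        s_star = _pooled_composition([pool[i] for i in idx[:n_s]])
        b_star = _pooled_composition([pool[i] for i in idx[n_s:]])
        b_star = np.where(b_star == 0, 1e-12, b_star)
        null = (s_star - b_star) / b_star
        exceed += np.abs(null) >= np.abs(observed)
    pvals = (1.0 + exceed) / (n_boot + 1.0)
    return GroupRAACReport(
        relative_difference={a: float(observed[i]) for i, a in enumerate(AA_ORDER)},
        p_value={a: float(pvals[i]) for i, a in enumerate(AA_ORDER)},
        n_boot=n_boot,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Secondary structure (SS block)
# ---------------------------------------------------------------------------

def collapse_runs(ss: SSAnnotation) -> list[SSRun]:
    """Collapse a state string into maximal constant-state runs."""
    states = ss.states
    if not states:
        raise ValueError("empty secondary-structure string")
    runs: list[SSRun] = []
    start = 0
    for i in range(1, len(states) + 1):
        if i == len(states) or states[i] != states[start]:
            runs.append(SSRun(states[start], start, i - start))
            start = i
    return runs


def ss_features(ss: SSAnnotation) -> np.ndarray:
    """The 39 secondary-structure features.

    Layout: 3 state-content values for (C, H, E) — mean per-residue
    probabilities when available, otherwise state fractions — then for
    each of the 12 motifs, in order: the fraction of residues covered by
    at least one occurrence of the motif, the motif's fraction of all
    motif occurrences (0 when there are none), and the mean motif length
    divided by L.  Motif occurrences are all overlapping windows of
    three consecutive runs.
    """
    L = len(ss.states)
    if ss.probs is not None:
        contents = ss.probs.mean(axis=0)  # (C, H, E) column order
    else:
        contents = np.array([ss.states.count(s) / L for s in "CHE"])

    runs = collapse_runs(ss)
    windows = [tuple(runs[i : i + 3]) for i in range(len(runs) - 2)]
    total_windows = len(windows)

    covered: dict[str, set[int]] = {m: set() for m in SS_MOTIFS}
    occurrences: dict[str, int] = {m: 0 for m in SS_MOTIFS}
    lengths: dict[str, list[int]] = {m: [] for m in SS_MOTIFS}
    for w in windows:
        motif = "".join(r.state for r in w)
        occurrences[motif] += 1
        span = sum(r.length for r in w)
        lengths[motif].append(span)
        covered[motif].update(range(w[0].start, w[0].start + span))

    out = [*contents]
    for m in SS_MOTIFS:
        resfrac = len(covered[m]) / L
        motiffrac = occurrences[m] / total_windows if total_windows else 0.0
        meanlen = (np.mean(lengths[m]) / L) if lengths[m] else 0.0
        out += [resfrac, motiffrac, meanlen]
    return np.array(out, dtype=float)


# ---------------------------------------------------------------------------
# Evolutionary conservation (EC block)
# ---------------------------------------------------------------------------

def ec_features(pssm: PSSMProfile, seq: str) -> np.ndarray:
    """The 400 logistic-normalised substitution-preference values.

    ``S_ij`` sums the PSSM log-odds for target type j over all positions
    carrying residue type i; the output is ``1 / (1 + exp(-S_ij / L))``
    flattened row-major over (i, j) in PSI-BLAST letter order.  The
    division by the sequence length L makes the encoding invariant to
    duplicating the sequence.  X positions contribute to no row and are
    excluded from L.
    """
    if pssm.scores.shape[0] != len(seq):
        raise ValueError(
            f"PSSM rows ({pssm.scores.shape[0]}) != sequence length ({len(seq)})"
        )
    S = np.zeros((20, 20))
    eff_len = 0
    for pos, ch in enumerate(seq):
        idx = _AA_INDEX.get(ch)
        if idx is None:
            continue
        S[idx] += pssm.scores[pos]
        eff_len += 1
    if eff_len == 0:
        raise ValueError("sequence has no canonical residues")
    return (1.0 / (1.0 + np.exp(-S / eff_len))).ravel()


# ---------------------------------------------------------------------------
# Physicochemical properties (PP block)
# ---------------------------------------------------------------------------

def pp_features(seq: str, scales: Optional[PropertyScaleSet] = None) -> np.ndarray:
    """Mean residue-class membership for each of the eleven properties."""
    if scales is None:
        scales = default_property_scales()
    comp = composition(seq)  # raises on an all-X sequence
    out = np.empty(len(PROPERTY_NAMES))
    for k, name in enumerate(PROPERTY_NAMES):
        member = np.array([scales.classes[name][a] for a in AA_ORDER])
        out[k] = float(comp @ member)
    return out


# ---------------------------------------------------------------------------
# Full encoder
# ---------------------------------------------------------------------------

def encode_protein(
    record: ProteinRecord,
    pssm: PSSMProfile,
    ss: SSAnnotation,
    background: Optional[BackgroundComposition] = None,
    scales: Optional[PropertyScaleSet] = None,
    raac_mode: str = "relative",
) -> FeatureVector:
    """Encode one protein into the fixed 470-value vector.

    ``raac_mode`` selects whether the first block is the raw composition
    (``"raw"``) or the relative composition against the background
    (``"relative"``, the default).
    """
    if background is None:
        background = default_background()
    if raac_mode not in ("raw", "relative"):
        raise ValueError(f"unknown raac_mode {raac_mode!r}")
    if len(ss.states) != len(record.sequence):
        raise ValueError(
            f"{record.id}: SS length {len(ss.states)} != sequence length {len(record)}"
        )
    try:
        comp = composition(record.sequence)
        raac = comp if raac_mode == "raw" else relative_composition(comp, background)
        blocks = [
            raac,
            ss_features(ss),
            ec_features(pssm, record.sequence),
            pp_features(record.sequence, scales),
        ]
    except ValueError as exc:
        raise ValueError(f"{record.id}: {exc}") from exc
    return FeatureVector(record.id, np.concatenate(blocks), feature_schema())
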