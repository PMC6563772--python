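"""Synthetic inputs for the whole pipeline: no external data required.

Two generator families:

* :func:`gen_planted_dataset` — class-conditional spherical Gaussian
  feature matrices with a planted set of informative dimensions.  With
  effect size ``d`` per informative dimension and ``k`` informative
  dimensions, the Bayes-optimal linear score has AUC
  ``Phi(d * sqrt(k) / sqrt(2))``, so recovery and classification
  behaviour can be checked against closed forms.

* secretory-like protein corpora — sequences drawn i.i.d. from a
  composition tilted the way plasma secretory proteins are (threonine
  and cysteine enriched; lysine, glutamine, arginine depleted), with
  run-structured three-state secondary structure from a first-order
  Markov chain and PSSM-like conservation profiles.  The tilt
  reproduces the direction of the observed composition differences,
  not their magnitudes.

Every generator is a pure function of (spec, seed): identical inputs
give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .io_formats import (
    AA_ORDER,
    LabeledDataset,
    ProteinRecord,
    PSSMProfile,
    SSAnnotation,
    write_fasta,
    write_labels,
    write_pssm,
    write_ss2,
)
from .features import SWISSPROT_BACKGROUND

__all__ = [
    "PlantedDatasetSpec",
    "SecretoryLikeSpec",
    "DEFAULT_TILT",
    "gen_planted_dataset",
    "gen_sequences",
    "gen_ss",
    "gen_pssm",
    "gen_end_to_end_corpus",
]

# Log-fold composition tilt applied to the positive (secretory-like)
# class: direction of the known enrichment/depletion pattern.
DEFAULT_TILT: dict[str, float] = {"T": 0.38, "C": 0.10, "K": -0.10, "Q": -0.12, "R": -0.14}


@dataclass
class PlantedDatasetSpec:
    n_pos: int = 100
    n_neg: int = 100
    n_features: int = 100
    informative: tuple[int, ...] = (0, 1, 2, 3, 4, 5, 6, 7)
    effect_size: float = 1.5
    noise_sd: float = 1.0
    duplicate_map: Optional[dict[int, int]] = None  # target column -> source column
    seed: int = 0

    def __post_init__(self) -> None:
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if any(not 0 <= i < self.n_features for i in self.informative):
            raise ValueError("informative indices out of range")


@dataclass
class SecretoryLikeSpec:
    n_per_class: int = 80
    length_range: tuple[int, int] = (120, 400)
    tilt: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_TILT))
    ss_mean_run_length: dict[str, float] = field(
        default_factory=lambda: {"H": 8.0, "E": 5.0, "C": 6.0}
    )
    conservation: float = 0.8
    pssm_noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length_range[0] < 50:
            # mirrors the benchmark-construction length filter
            raise ValueError("minimum length must be >= 50 residues")
        if not 0 <= self.conservation <= 1:
            raise ValueError("conservation must lie in [0, 1]")
        if any(v < 1 for v in self.ss_mean_run_length.values()):
            raise ValueError("mean run lengths must be >= 1")


# ---------------------------------------------------------------------------
# Planted feature matrices
# ---------------------------------------------------------------------------

def gen_planted_dataset(spec: PlantedDatasetSpec) -> LabeledDataset:
    """Class-conditional Gaussian features with planted informative dims.

    Positives have mean ``effect_size * noise_sd`` on informative
    dimensions; all other dimensions are exchangeable noise.  Optional
    exact column duplicates are applied afterwards.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_pos + spec.n_neg
    X = rng.normal(0.0, spec.noise_sd, size=(n, spec.n_features))
    y = np.r_[np.ones(spec.n_pos, dtype=int), np.zeros(spec.n_neg, dtype=int)]
    shift = spec.effect_size * spec.noise_sd
    for j in spec.informative:
        X[: spec.n_pos, j] += shift
    if spec.duplicate_map:
        for target, source in spec.duplicate_map.items():
            X[:, target] = X[:, source]
    ids = [f"sim{i:05d}" for i in range(n)]
    schema = [f"F{j:03d}" for j in range(spec.n_features)]
    return LabeledDataset(ids=ids, X=X, y=y, schema=schema)


# ---------------------------------------------------------------------------
# Sequences, secondary structure, PSSMs
# ---------------------------------------------------------------------------

def _class_composition(tilt: dict[str, float], apply_tilt: bool) -> np.ndarray:
    base = np.array([SWISSPROT_BACKGROUND[a] for a in AA_ORDER])
    base = base / base.sum()
    if not apply_tilt:
        return base
    logfold = np.array([tilt.get(a, 0.0) for a in AA_ORDER])
    tilted = base * np.exp(logfold)
    return tilted / tilted.sum()


def gen_sequences(spec: SecretoryLikeSpec, class_label: int,
                  rng: Optional[np.random.Generator] = None) -> list[ProteinRecord]:
    """i.i.d. residues from the class composition; lengths uniform in range.

    ``class_label = 1`` applies the secretory-like tilt; 0 uses the
    untilted background.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed + class_label)
    comp = _class_composition(spec.tilt, apply_tilt=bool(class_label))
    prefix = "pos" if class_label else "neg"
    lo, hi = spec.length_range
    records = []
    letters = np.array(list(AA_ORDER))
    for i in range(spec.n_per_class):
        L = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(letters, size=L, p=comp))
        records.append(ProteinRecord(f"{prefix}{i:04d}", seq))
    return records


def gen_ss(record: ProteinRecord, spec: SecretoryLikeSpec,
           rng: Optional[np.random.Generator] = None) -> SSAnnotation:
    """Run-structured secondary structure from a first-order Markov chain.

    Stay-probability for state s is ``1 - 1/mean_run_length[s]``
    (geometric run lengths with the requested mean); on leaving, the two
    other states are equally likely.  Probability rows put 0.8 on the
    emitted state and 0.1 on each other.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    states_order = "HEC"
    stay = {s: 1.0 - 1.0 / spec.ss_mean_run_length[s] for s in states_order}
    L = len(record.sequence)
    out = []
    current = states_order[int(rng.integers(0, 3))]
    for _ in range(L):
        out.append(current)
        if rng.random() >= stay[current]:
            others = [s for s in states_order if s != current]
            current = others[int(rng.integers(0, 2))]
    states = "".join(out)
    probs = np.full((L, 3), 0.1)
    for i, s in enumerate(states):  # columns are (C, H, E)
        probs[i, "CHE".index(s)] = 0.8
    return SSAnnotation(record.id, states, probs)


def gen_pssm(record: ProteinRecord, conservation: float,
             rng: Optional[np.random.Generator] = None,
             noise_sd: float = 2.0, seed: int = 0) -> PSSMProfile:
    """PSSM-like integer profile emulating a conservation signal.

    Each row scores ``+7 * conservation`` at the true residue's column
    and ``-2 * conservation`` elsewhere, plus rounded Gaussian noise,
    clamped to the PSI-BLAST-typical integer range [-10, 12].  X
    positions carry noise only.
    """
    if not 0 <= conservation <= 1:
        raise ValueError("conservation must lie in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(seed)
    L = len(record.sequence)
    base = np.full((L, 20), -2.0 * conservation)
    aa_index = {a: i for i, a in enumerate(AA_ORDER)}
    for pos, ch in enumerate(record.sequence):
        idx = aa_index.get(ch)
        if idx is None:
            base[pos, :] = 0.0
        else:
            base[pos, idx] = 7.0 * conservation
    if noise_sd > 0:
        base = base + rng.normal(0.0, noise_sd, size=base.shape)
    scores = np.clip(np.rint(base), -10, 12)
    return PSSMProfile(record.id, scores)


# ---------------------------------------------------------------------------
# On-disk corpus
# ---------------------------------------------------------------------------

def gen_end_to_end_corpus(spec: SecretoryLikeSpec, outdir: str | Path,
                          overwrite: bool = False) -> dict[str, Path]:
    """Write a complete input corpus: FASTA, per-protein PSSM and ss2, labels.

    Layout::

        outdir/
          sequences.fasta
          labels.tsv
          pssm/<id>.pssm
          ss2/<id>.ss2

    Regeneration from the same (spec, seed) is byte-identical.
    """
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not overwrite:
        raise FileExistsError(f"{outdir} exists and is not empty (use overwrite)")
    (outdir / "pssm").mkdir(parents=True, exist_ok=True)
    (outdir / "ss2").mkdir(parents=True, exist_ok=True)

    records: list[ProteinRecord] = []
    labels: dict[str, int] = {}
    for label in (1, 0):
        rng = np.random.default_rng(spec.seed * 4 + 1 + label)
        recs = gen_sequences(spec, label, rng=rng)
        for rec in recs:
            labels[rec.id] = label
        records.extend(recs)

    ann_rng = np.random.default_rng(spec.seed * 4 + 3)
    for rec in records:
        ss = gen_ss(rec, spec, rng=ann_rng)
        pssm = gen_pssm(rec, spec.conservation, rng=ann_rng, noise_sd=spec.pssm_noise_sd)
        write_ss2(ss, outdir / "ss2" / f"{rec.id}.ss2", sequence=rec.sequence)
        write_pssm(pssm, outdir / "pssm" / f"{rec.id}.pssm", sequence=rec.sequence)

    fasta = outdir / "sequences.fasta"
    write_fasta(records, fasta)
    labels_path = outdir / "labels.tsv"
    write_labels(labels, labels_path)
    return {
        "fasta": fasta,
        "labels": labels_path,
        "pssm_dir": outdir / "pssm",
        "ss2_dir": outdir / "ss2",
    }
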