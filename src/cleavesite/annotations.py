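"""Per-residue structural annotation: predictor-output readers and a built-in heuristic.

Cleavage sites are enriched in coil, solvent-exposed and natively disordered
regions, so three structural channels accompany the sequence: three-state
secondary structure (H helix, E strand, C coil/other) with per-state
probabilities, two-state solvent accessibility (e exposed, b buried) and
two-state native disorder (``*`` disordered, ``.`` ordered).  The readers
accept the common vertical/flat output dialects of secondary-structure,
accessibility and disorder predictors; the heuristic annotator is a
deterministic, dependency-free stand-in (physico-chemical rules only, no
accuracy claim) so the pipeline runs without any external predictor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .substrates import GAP

logger = logging.getLogger(__name__)

SS_STATES = "HEC"
SA_STATES = "eb"
DISO_STATES = "*."


class AnnotationParseError(ValueError):
    """Raised on a malformed predictor-output line."""


class AnnotationAlignmentError(ValueError):
    """Raised when an annotation does not align with its sequence."""


@dataclass
class StructuralAnnotation:
    """Aligned per-residue structural states for one substrate."""

    substrate_id: str
    ss_states: str
    ss_probs: np.ndarray  # (n, 3) columns H, E, C
    sa_states: str
    disorder_states: str
    disorder_probs: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ss_states)
        self.ss_probs = np.asarray(self.ss_probs, dtype=float)
        self.disorder_probs = np.asarray(self.disorder_probs, dtype=float)
        if not (len(self.sa_states) == len(self.disorder_states) == n):
            raise AnnotationAlignmentError(f"{self.substrate_id}: channel lengths differ")
        if self.ss_probs.shape != (n, 3):
            raise AnnotationAlignmentError(f"{self.substrate_id}: ss_probs shape {self.ss_probs.shape}")
        if self.disorder_probs.shape != (n,):
            raise AnnotationAlignmentError(f"{self.substrate_id}: disorder_probs shape")
        sums = self.ss_probs.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-3):
            raise AnnotationAlignmentError(
                f"{self.substrate_id}: ss probability rows do not sum to 1 (predictor files are rounded; tolerance 1e-3)"
            )
        if any(c not in SS_STATES for c in self.ss_states):
            raise AnnotationAlignmentError(f"{self.substrate_id}: bad SS state letters")
        if any(c not in SA_STATES for c in self.sa_states):
            raise AnnotationAlignmentError(f"{self.substrate_id}: bad SA state letters")
        if any(c not in DISO_STATES for c in self.disorder_states):
            raise AnnotationAlignmentError(f"{self.substrate_id}: bad disorder state letters")

    def __len__(self) -> int:
        return len(self.ss_states)


# ---------------------------------------------------------------------------
# predictor-output parsers


def parse_ss_prediction(path, sequence: str | None = None) -> tuple[str, np.ndarray]:
    """Read a vertical three-state secondary-structure prediction.

    Expected columns per line: index, residue, state letter (H/E/C), then the
    three state probabilities in H, E, C order.  Comment lines (``#``) and
    blanks are skipped.  If the state letter disagrees with the argmax of the
    probability columns, a warning is emitted and the letter wins.
    """
    states: list[str] = []
    probs: list[list[float]] = []
    residues: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 6:
                raise AnnotationParseError(f"{path}:{lineno}: expected 6 columns, got {len(parts)}")
            try:
                triple = [float(parts[3]), float(parts[4]), float(parts[5])]
            except ValueError as exc:
                raise AnnotationParseError(f"{path}:{lineno}: bad probability column") from exc
            letter = parts[2].upper()
            if letter not in SS_STATES:
                raise AnnotationParseError(f"{path}:{lineno}: bad state letter {letter!r}")
            if SS_STATES[int(np.argmax(triple))] != letter:
                logger.warning("%s:%d: state letter %s disagrees with argmax of probabilities; letter wins",
                               path, lineno, letter)
            residues.append(parts[1].upper())
            states.append(letter)
            probs.append(triple)
    _check_residues(path, residues, sequence)
    return "".join(states), np.asarray(probs, dtype=float)


def parse_sa_prediction(path, sequence: str | None = None) -> str:
    """Read a flat two-state accessibility string (one letter per residue, e/b).

    Lines starting with ``>`` or ``#`` are headers/comments; remaining lines
    are concatenated.  Mixed case is normalised to lower case.
    """
    chunks = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith((">", "#")):
                continue
            chunk = line.lower()
            if any(c not in SA_STATES for c in chunk):
                raise AnnotationParseError(f"{path}:{lineno}: non e/b character in accessibility string")
            chunks.append(chunk)
    states = "".join(chunks)
    if sequence is not None and len(states) != len(sequence):
        raise AnnotationAlignmentError(
            f"{path}: accessibility length {len(states)} != sequence length {len(sequence)}"
        )
    return states


def parse_disorder_prediction(path, sequence: str | None = None) -> tuple[str, np.ndarray]:
    """Read a vertical star/dot disorder prediction with optional probability column.

    Columns per line: index, residue, state (``*`` or ``.``) and optionally the
    disorder probability.  When the probability column is absent it is imputed
    as 0.9 for ``*`` and 0.1 for ``.``.
    """
    states: list[str] = []
    probs: list[float] = []
    residues: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise AnnotationParseError(f"{path}:{lineno}: expected >= 3 columns")
            state = parts[2]
            if state not in DISO_STATES:
                raise AnnotationParseError(f"{path}:{lineno}: bad disorder state {state!r}")
            if len(parts) >= 4:
                try:
                    prob = float(parts[3])
                except ValueError as exc:
                    raise AnnotationParseError(f"{path}:{lineno}: bad probability column") from exc
            else:
                prob = 0.9 if state == "*" else 0.1
            residues.append(parts[1].upper())
            states.append(state)
            probs.append(prob)
    _check_residues(path, residues, sequence)
    return "".join(states), np.asarray(probs, dtype=float)


def _check_residues(path, residues: list[str], sequence: str | None) -> None:
    if sequence is None:
        return
    if len(residues) != len(sequence):
        raise AnnotationAlignmentError(
            f"{path}: {len(residues)} annotated residues != sequence length {len(sequence)}"
        )
    for i, (r, s) in enumerate(zip(residues, sequence), start=1):
        if r != s and r != "X" and s != "X":
            raise AnnotationAlignmentError(f"{path}: residue mismatch at position {i}: {r} vs {s}")


# symmetric writers (round-trip fixtures and synthetic-data output)


def write_ss_prediction(path, sequence: str, states: str, probs: np.ndarray) -> None:
    with open(path, "w") as fh:
        fh.write("# idx res state pH pE pC\n")
        for i, (res, st, row) in enumerate(zip(sequence, states, probs), start=1):
            fh.write(f"{i} {res} {st} {row[0]:.3f} {row[1]:.3f} {row[2]:.3f}\n")


def write_sa_prediction(path, substrate_id: str, states: str) -> None:
    with open(path, "w") as fh:
        fh.write(f">{substrate_id}\n")
        for i in range(0, len(states), 60):
            fh.write(states[i : i + 60] + "\n")


def write_disorder_prediction(path, sequence: str, states: str, probs: np.ndarray) -> None:
    with open(path, "w") as fh:
        fh.write("# idx res state p\n")
        for i, (res, st, p) in enumerate(zip(sequence, states, probs), start=1):
            fh.write(f"{i} {res} {st} {p:.3f}\n")


def write_annotation(annotation: StructuralAnnotation, directory, sequence: str) -> None:
    """Write the three channel files ``<substrate_id>.{ss,sa,diso}``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    sid = annotation.substrate_id
    write_ss_prediction(directory / f"{sid}.ss", sequence, annotation.ss_states, annotation.ss_probs)
    write_sa_prediction(directory / f"{sid}.sa", sid, annotation.sa_states)
    write_disorder_prediction(
        directory / f"{sid}.diso", sequence, annotation.disorder_states, annotation.disorder_probs
    )


def load_annotations(directory, dataset) -> dict[str, StructuralAnnotation]:
    """Load ``<substrate_id>.{ss,sa,diso}`` files for every substrate in a dataset."""
    directory = Path(directory)
    out: dict[str, StructuralAnnotation] = {}
    for rec in dataset.substrates:
        sid = rec.substrate_id
        ss_states, ss_probs = parse_ss_prediction(directory / f"{sid}.ss", rec.sequence)
        sa_states = parse_sa_prediction(directory / f"{sid}.sa", rec.sequence)
        diso_states, diso_probs = parse_disorder_prediction(directory / f"{sid}.diso", rec.sequence)
        out[sid] = StructuralAnnotation(
            substrate_id=sid,
            ss_states=ss_states,
            ss_probs=ss_probs,
            sa_states=sa_states,
            disorder_states=diso_states,
            disorder_probs=diso_probs,
        )
    return out


# ---------------------------------------------------------------------------
# heuristic annotator

# Kyte-Doolittle hydropathy
_KD = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5, "E": -3.5,
    "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8,
    "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2, "X": 0.0,
}
# Chou-Fasman-style helix / strand propensities
_P_HELIX = {
    "A": 1.42, "R": 0.98, "N": 0.67, "D": 1.01, "C": 0.70, "Q": 1.11, "E": 1.51,
    "G": 0.57, "H": 1.00, "I": 1.08, "L": 1.21, "K": 1.16, "M": 1.45, "F": 1.13,
    "P": 0.57, "S": 0.77, "T": 0.83, "W": 1.08, "Y": 0.69, "V": 1.06, "X": 1.0,
}
_P_STRAND = {
    "A": 0.83, "R": 0.93, "N": 0.89, "D": 0.54, "C": 1.19, "Q": 1.10, "E": 0.37,
    "G": 0.75, "H": 0.87, "I": 1.60, "L": 1.30, "K": 0.74, "M": 1.05, "F": 1.38,
    "P": 0.55, "S": 0.75, "T": 1.19, "W": 1.37, "Y": 1.47, "V": 1.70, "X": 1.0,
}


def _window_mean(values: np.ndarray, half: int) -> np.ndarray:
    n = len(values)
    out = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        out[i] = values[lo:hi].mean()
    return out


def heuristic_annotate(sequence: str, seed: int = 0) -> StructuralAnnotation:
    """Deterministic physico-chemical stand-in annotator.

    Sliding-window hydropathy calls exposed/buried; smoothed helix/strand
    propensities (coil baseline 1.0) call the secondary-structure state;
    hydrophilicity combined with local low complexity calls disorder.  The
    output satisfies the :class:`StructuralAnnotation` invariants but carries
    no predictive accuracy claim; it exists so scanning and training run with
    no external predictor installed.
    """
    if not sequence:
        raise ValueError("empty sequence")
    sequence = sequence.upper()
    n = len(sequence)
    rng = np.random.default_rng(seed)
    jitter = rng.uniform(-1e-6, 1e-6, size=(n, 3))  # deterministic tie-break only

    kd = np.array([_KD.get(c, 0.0) for c in sequence])
    kd_mean = _window_mean(kd, half=4)
    sa_states = "".join("b" if v > 0.0 else "e" for v in kd_mean)

    ph = _window_mean(np.array([_P_HELIX.get(c, 1.0) for c in sequence]), half=2)
    pe = _window_mean(np.array([_P_STRAND.get(c, 1.0) for c in sequence]), half=2)
    raw = np.column_stack([ph, pe, np.ones(n)]) + jitter
    ss_probs = raw / raw.sum(axis=1, keepdims=True)
    ss_states = "".join(SS_STATES[int(i)] for i in np.argmax(ss_probs, axis=1))

    complexity = np.empty(n)
    half = 6
    for i in range(n):
        seg = sequence[max(0, i - half) : i + half + 1]
        complexity[i] = len(set(seg)) / min(len(seg), 20)
    diso_raw = 0.5 - kd_mean / 9.0 + 0.3 * (1.0 - complexity)
    disorder_probs = np.clip(diso_raw, 0.01, 0.99)
    disorder_states = "".join("*" if p > 0.5 else "." for p in disorder_probs)

    return StructuralAnnotation(
        substrate_id="<heuristic>",
        ss_states=ss_states,
        ss_probs=ss_probs,
        sa_states=sa_states,
        disorder_states=disorder_states,
        disorder_probs=disorder_probs,
    )
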