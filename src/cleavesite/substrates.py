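"""Substrate collections: data model, I/O, window extraction and redundancy reduction.

A protease substrate is a protein sequence carrying one or more experimentally
annotated cleavage sites.  Following the Schechter–Berger convention, residues
are numbered outward from the scissile bond: ...P4-P3-P2-P1 | P1'-P2'-P3'-P4'...
The P1 position (1-based index of the residue N-terminal to the cut) identifies
a site; a window ``Pa–Pb'`` spans sequence indices ``p1-a+1 .. p1+b`` and has
length ``L = a + b``.  Windows that overrun a terminus are padded with a
reserved gap symbol so the vector length stays fixed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import Align, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: the 20 standard amino acids, alphabetical one-letter codes
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
#: placeholder for residues outside the sequence (terminal padding)
GAP = "-"
#: unknown residue
UNKNOWN = "X"

_VALID_RESIDUES = frozenset(AA_ALPHABET + UNKNOWN)

LABEL_CLEAVED = "cleaved"
LABEL_NONCLEAVED = "non-cleaved"


class SubstrateValidationError(ValueError):
    """Raised when a substrate record violates its invariants."""


class DatasetLoadError(ValueError):
    """Raised when substrate files cannot be reconciled."""


def subsite_labels(span: tuple[int, int]) -> list[str]:
    """Schechter–Berger labels for a ``Pa–Pb'`` window, N- to C-terminal.

    >>> subsite_labels((4, 2))
    ['P4', 'P3', 'P2', 'P1', "P1'", "P2'"]
    """
    a, b = span
    return [f"P{a - i}" for i in range(a)] + [f"P{j + 1}'" for j in range(b)]


@dataclass
class SubstrateRecord:
    """One substrate sequence with its annotated P1 cleavage positions."""

    substrate_id: str
    protease_id: str
    sequence: str
    cleavage_p1_positions: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if not self.sequence:
            raise SubstrateValidationError(f"{self.substrate_id}: empty sequence")
        seq = self.sequence.upper()
        cleaned = "".join(c if c in _VALID_RESIDUES else UNKNOWN for c in seq)
        if cleaned != seq:
            bad = sorted({c for c in seq if c not in _VALID_RESIDUES})
            logger.debug("%s: mapping non-standard residues %s to X", self.substrate_id, bad)
        self.sequence = cleaned
        positions = tuple(sorted(set(int(p) for p in self.cleavage_p1_positions)))
        for p in positions:
            if not 1 <= p < len(self.sequence):
                raise SubstrateValidationError(
                    f"{self.substrate_id}: P1 position {p} out of range "
                    f"(must satisfy 1 <= p < {len(self.sequence)}; a P1' residue must exist)"
                )
        self.cleavage_p1_positions = positions

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ProteaseDataset:
    """A collection of substrates of one protease."""

    protease_id: str
    substrates: list[SubstrateRecord] = field(default_factory=list)
    merops_id: str | None = None

    def __post_init__(self) -> None:
        ids = [s.substrate_id for s in self.substrates]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise SubstrateValidationError(f"duplicate substrate ids: {dup}")

    @property
    def n_substrates(self) -> int:
        return len(self.substrates)

    @property
    def n_sites(self) -> int:
        return sum(len(s.cleavage_p1_positions) for s in self.substrates)

    @property
    def substrate_ids(self) -> list[str]:
        return [s.substrate_id for s in self.substrates]

    def get(self, substrate_id: str) -> SubstrateRecord:
        for s in self.substrates:
            if s.substrate_id == substrate_id:
                return s
        raise KeyError(substrate_id)

    def subset(self, substrate_ids) -> "ProteaseDataset":
        wanted = set(substrate_ids)
        return ProteaseDataset(
            protease_id=self.protease_id,
            merops_id=self.merops_id,
            substrates=[s for s in self.substrates if s.substrate_id in wanted],
        )


@dataclass
class SiteWindow:
    """A labelled candidate cleavage site with its local Pa–Pb' context.

    ``residues`` has length ``L = a + b``; offset ``a-1`` (0-based) is the P1
    residue unless it falls in terminal padding.  Structural channels, when
    present, are aligned strings of the same length over {H,E,C}, {e,b} and
    {*,.} respectively, gap-padded like the residues.
    """

    substrate_id: str
    p1_index: int
    span: tuple[int, int]
    residues: str
    label: str
    ss: str | None = None
    sa: str | None = None
    diso: str | None = None

    def __post_init__(self) -> None:
        a, b = self.span
        L = a + b
        if len(self.residues) != L:
            raise SubstrateValidationError(
                f"window residues length {len(self.residues)} != span length {L}"
            )
        for name in ("ss", "sa", "diso"):
            chan = getattr(self, name)
            if chan is not None and len(chan) != L:
                raise SubstrateValidationError(f"channel {name} length != {L}")
        if self.label not in (LABEL_CLEAVED, LABEL_NONCLEAVED):
            raise SubstrateValidationError(f"bad label {self.label!r}")

    @property
    def is_positive(self) -> bool:
        return self.label == LABEL_CLEAVED

    @property
    def length(self) -> int:
        return self.span[0] + self.span[1]


def padded_slice(s: str, start0: int, length: int, gap: str = GAP) -> str:
    """Slice ``s`` at 0-based ``start0`` for ``length`` chars, gap-padding out-of-range."""
    return "".join(s[i] if 0 <= i < len(s) else gap for i in range(start0, start0 + length))


def make_window(
    record: SubstrateRecord,
    p1: int,
    span: tuple[int, int],
    label: str,
    annotation=None,
) -> SiteWindow:
    """Cut the ``Pa–Pb'`` window around a 1-based P1 index, aligning structure if given."""
    a, b = span
    start0 = p1 - a  # 0-based index of the Pa residue
    L = a + b
    kwargs = {}
    if annotation is not None:
        kwargs["ss"] = padded_slice(annotation.ss_states, start0, L)
        kwargs["sa"] = padded_slice(annotation.sa_states, start0, L)
        kwargs["diso"] = padded_slice(annotation.disorder_states, start0, L)
    return SiteWindow(
        substrate_id=record.substrate_id,
        p1_index=p1,
        span=span,
        residues=padded_slice(record.sequence, start0, L),
        label=label,
        **kwargs,
    )


def extract_windows(
    dataset: ProteaseDataset,
    span: tuple[int, int] = (4, 2),
    negative_ratio: float = 3.0,
    seed: int = 0,
    annotations: dict | None = None,
) -> list[SiteWindow]:
    """Extract labelled site windows: all positives plus sampled negatives.

    One positive window per annotated P1.  Negatives are drawn uniformly at
    random without replacement (seeded) from the global pool of non-annotated
    candidate P1 positions (``1 .. len-1``), downsampled to
    ``floor(negative_ratio * n_positives)``.  If the pool is smaller than the
    request, all candidates are returned and a warning is logged.
    """
    a, b = span
    if a < 1 or b < 1:
        raise ValueError("span sides must be >= 1")
    if negative_ratio <= 0:
        raise ValueError("negative_ratio must be > 0")
    annotations = annotations or {}

    positives: list[SiteWindow] = []
    candidates: list[tuple[str, int]] = []
    for rec in dataset.substrates:
        ann = annotations.get(rec.substrate_id)
        annotated = set(rec.cleavage_p1_positions)
        for p1 in rec.cleavage_p1_positions:
            positives.append(make_window(rec, p1, span, LABEL_CLEAVED, ann))
        for p1 in range(1, len(rec.sequence)):
            if p1 not in annotated:
                candidates.append((rec.substrate_id, p1))

    n_neg = math.floor(negative_ratio * len(positives))
    rng = np.random.default_rng(seed)
    if len(candidates) < n_neg:
        logger.warning(
            "only %d negative candidates available for %d requested; using all",
            len(candidates),
            n_neg,
        )
        chosen = list(range(len(candidates)))
    else:
        chosen = sorted(rng.choice(len(candidates), size=n_neg, replace=False).tolist())

    negatives = []
    for idx in chosen:
        sid, p1 = candidates[idx]
        rec = dataset.get(sid)
        negatives.append(make_window(rec, p1, span, LABEL_NONCLEAVED, annotations.get(sid)))
    return positives + negatives


def specificity_profile(dataset: ProteaseDataset, span: tuple[int, int] = (6, 6)) -> pd.DataFrame:
    """Position-by-residue frequency matrix over annotated cleavage sites.

    Rows are subsites (Pa..Pb'), columns the 20 amino acids.  Terminal padding
    and X are excluded from the per-position normalisation; each row with at
    least one observed residue sums to 1.
    """
    if dataset.n_sites == 0:
        raise ValueError("dataset has no annotated cleavage sites")
    L = span[0] + span[1]
    counts = np.zeros((L, len(AA_ALPHABET)), dtype=float)
    aa_index = {aa: i for i, aa in enumerate(AA_ALPHABET)}
    for rec in dataset.substrates:
        for p1 in rec.cleavage_p1_positions:
            window = padded_slice(rec.sequence, p1 - span[0], L)
            for i, sym in enumerate(window):
                if sym in aa_index:
                    counts[i, aa_index[sym]] += 1
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        freqs = np.where(totals > 0, counts / totals, 0.0)
    return pd.DataFrame(freqs, index=subsite_labels(span), columns=list(AA_ALPHABET))


# ---------------------------------------------------------------------------
# redundancy reduction


def _pairwise_identity(aligner: Align.PairwiseAligner, s1: str, s2: str) -> float:
    aln = aligner.align(s1, s2)[0]
    counts = aln.counts()
    length = counts.gaps + counts.identities + counts.mismatches
    return counts.identities / length if length else 0.0


def reduce_redundancy(dataset: ProteaseDataset, identity_threshold: float = 0.7) -> ProteaseDataset:
    """Greedy longest-first homology reduction.

    Sequences are visited longest-first; each joins the first retained
    representative it matches at >= ``identity_threshold`` global-alignment
    identity (identities / alignment length), otherwise it becomes a new
    representative.  One representative (the longest member) survives per
    cluster.  This is a documented greedy approximation of external clustering
    tools such as CD-HIT, and it is idempotent.
    """
    if not 0 < identity_threshold <= 1:
        raise ValueError("identity_threshold must be in (0, 1]")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -1.0
    aligner.extend_gap_score = -0.5

    ordered = sorted(dataset.substrates, key=lambda r: (-len(r.sequence), r.substrate_id))
    representatives: list[SubstrateRecord] = []
    for rec in ordered:
        if not any(
            _pairwise_identity(aligner, rep.sequence, rec.sequence) >= identity_threshold
            for rep in representatives
        ):
            representatives.append(rec)
    keep = {r.substrate_id for r in representatives}
    return ProteaseDataset(
        protease_id=dataset.protease_id,
        merops_id=dataset.merops_id,
        substrates=[s for s in dataset.substrates if s.substrate_id in keep],
    )


# ---------------------------------------------------------------------------
# I/O

ANNOTATION_COLUMNS = ("substrate_id", "protease_id", "p1_positions")


def read_substrates(fasta_path, annotation_path) -> ProteaseDataset:
    """Load a substrate collection from FASTA + tab-delimited cleavage table.

    The annotation table has a header line ``substrate_id\\tprotease_id\\t
    p1_positions`` with comma-separated 1-based P1 indices per substrate.
    Every annotated id must have a sequence in the FASTA file.
    """
    sequences = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    table = pd.read_csv(annotation_path, sep="\t", dtype=str)
    missing_cols = set(ANNOTATION_COLUMNS) - set(table.columns)
    if missing_cols:
        raise DatasetLoadError(f"annotation table missing columns: {sorted(missing_cols)}")
    proteases = table["protease_id"].unique().tolist()
    if len(proteases) != 1:
        raise DatasetLoadError(f"annotation table mixes proteases: {proteases}")

    substrates = []
    for row in table.itertuples(index=False):
        sid = row.substrate_id
        if sid not in sequences:
            raise DatasetLoadError(f"no FASTA sequence for annotated substrate {sid!r}")
        raw = str(row.p1_positions).strip()
        positions = tuple(int(tok) for tok in raw.split(",") if tok.strip()) if raw else ()
        substrates.append(
            SubstrateRecord(
                substrate_id=sid,
                protease_id=row.protease_id,
                sequence=sequences[sid],
                cleavage_p1_positions=positions,
            )
        )
    return ProteaseDataset(protease_id=proteases[0], substrates=substrates)


def write_substrates(dataset: ProteaseDataset, fasta_path, annotation_path) -> None:
    """Write the FASTA + annotation-table pair that :func:`read_substrates` consumes."""
    records = [
        SeqRecord(Seq(s.sequence), id=s.substrate_id, description="")
        for s in dataset.substrates
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    rows = [
        {
            "substrate_id": s.substrate_id,
            "protease_id": s.protease_id,
            "p1_positions": ",".join(str(p) for p in s.cleavage_p1_positions),
        }
        for s in dataset.substrates
    ]
    pd.DataFrame(rows, columns=list(ANNOTATION_COLUMNS)).to_csv(
        annotation_path, sep="\t", index=False
    )
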