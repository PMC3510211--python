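"""Feature encoding: orthonormal sequence encoding and bi-profile Bayesian profiles.

A candidate site's ``Pa–Pb'`` window (length ``L``) is encoded by concatenating
named blocks:

``BEAA``
    binary (orthonormal, one-hot) encoding of the window residues; 20 values
    per position, gap/X encode as all-zeros (``L x 20`` values).
``BPBAA`` / ``BPBSS`` / ``BPBSA`` / ``BPBDISO``
    bi-profile Bayesian profiles of one annotation channel: per-position
    symbol frequency tables are fitted separately on cleaved (positive) and
    non-cleaved (negative) windows, and a window contributes, per position,
    the positive-profile and negative-profile frequency of its observed
    symbol (``L x 2`` values per block, all positive halves before all
    negative halves).

The full scheme ``ALL`` = BEAA+BPBAA+BPBSS+BPBSA+BPBDISO has
``L*20 + 4 * L*2 = 28 L`` elements: 168 for the P4–P2' window (L=6) and 448
for the extended P8–P8' window (L=16).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .substrates import AA_ALPHABET, GAP, SiteWindow, subsite_labels

CHANNEL_ALPHABETS: dict[str, str] = {
    "AA": AA_ALPHABET,
    "SS": "HEC",
    "SA": "eb",
    "DISO": "*.",
}

#: fixed block concatenation order
BLOCK_ORDER = ("BEAA", "BPBAA", "BPBSS", "BPBSA", "BPBDISO")

_BLOCK_CHANNEL = {"BPBAA": "AA", "BPBSS": "SS", "BPBSA": "SA", "BPBDISO": "DISO"}


class EncodingError(ValueError):
    pass


@dataclass
class BiProfile:
    """Positive/negative per-position symbol frequency tables for one channel.

    ``pos_freq[i, s] = (count of symbol s at position i among positives
    + pseudocount) / (observed positives at position i + pseudocount * |A|)``
    and analogously for ``neg_freq``; with a positive pseudocount every entry
    is > 0 and each row sums to 1.  Window positions holding the gap symbol
    (terminal padding) are excluded from the per-position counts and encode
    to the unseen-symbol frequency ``pseudocount / (n_class + pseudocount*|A|)``.
    """

    channel: str
    span: tuple[int, int]
    alphabet: str
    pos_freq: np.ndarray
    neg_freq: np.ndarray
    pseudocount: float
    gap_value_pos: float = 0.0
    gap_value_neg: float = 0.0

    def __post_init__(self) -> None:
        L = self.span[0] + self.span[1]
        A = len(self.alphabet)
        self.pos_freq = np.asarray(self.pos_freq, dtype=float)
        self.neg_freq = np.asarray(self.neg_freq, dtype=float)
        if self.pos_freq.shape != (L, A) or self.neg_freq.shape != (L, A):
            raise EncodingError(f"profile shape mismatch for channel {self.channel}")

    def to_tsv(self, path) -> None:
        labels = subsite_labels(self.span)
        rows = []
        for i, lab in enumerate(labels):
            for j, sym in enumerate(self.alphabet):
                rows.append(
                    {
                        "channel": self.channel,
                        "position": lab,
                        "symbol": sym,
                        "pos_freq": self.pos_freq[i, j],
                        "neg_freq": self.neg_freq[i, j],
                    }
                )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, span: tuple[int, int], pseudocount: float = 1.0) -> "BiProfile":
        df = pd.read_csv(path, sep="\t", dtype={"symbol": str})
        channel = df["channel"].iloc[0]
        alphabet = CHANNEL_ALPHABETS[channel]
        L = span[0] + span[1]
        labels = subsite_labels(span)
        pos = np.zeros((L, len(alphabet)))
        neg = np.zeros((L, len(alphabet)))
        pos_index = {lab: i for i, lab in enumerate(labels)}
        sym_index = {s: j for j, s in enumerate(alphabet)}
        for row in df.itertuples(index=False):
            pos[pos_index[row.position], sym_index[str(row.symbol)]] = row.pos_freq
            neg[pos_index[row.position], sym_index[str(row.symbol)]] = row.neg_freq
        return cls(channel=channel, span=span, alphabet=alphabet, pos_freq=pos, neg_freq=neg,
                   pseudocount=pseudocount)


def _channel_string(window: SiteWindow, channel: str) -> str:
    if channel == "AA":
        return window.residues
    attr = {"SS": "ss", "SA": "sa", "DISO": "diso"}[channel]
    value = getattr(window, attr)
    if value is None:
        raise EncodingError(
            f"window {window.substrate_id}@{window.p1_index} lacks the {channel} channel"
        )
    return value


def fit_biprofile(
    positives: list[SiteWindow],
    negatives: list[SiteWindow],
    channel: str,
    pseudocount: float = 1.0,
) -> BiProfile:
    """Fit per-position positive/negative symbol frequency tables."""
    if channel not in CHANNEL_ALPHABETS:
        raise EncodingError(f"unknown channel {channel!r}")
    if not positives or not negatives:
        raise EncodingError("both positive and negative window lists must be non-empty")
    span = positives[0].span
    for w in positives + negatives:
        if w.span != span:
            raise EncodingError(f"span mismatch: {w.span} vs {span}")
    alphabet = CHANNEL_ALPHABETS[channel]
    sym_index = {s: j for j, s in enumerate(alphabet)}
    L = span[0] + span[1]
    A = len(alphabet)

    def table(windows: list[SiteWindow]) -> np.ndarray:
        counts = np.zeros((L, A))
        observed = np.zeros(L)
        for w in windows:
            for i, sym in enumerate(_channel_string(w, channel)):
                j = sym_index.get(sym)
                if j is not None:
                    counts[i, j] += 1
                    observed[i] += 1
        denom = observed[:, None] + pseudocount * A
        return (counts + pseudocount) / denom

    gap_pos = pseudocount / (len(positives) + pseudocount * A)
    gap_neg = pseudocount / (len(negatives) + pseudocount * A)
    return BiProfile(
        channel=channel,
        span=span,
        alphabet=alphabet,
        pos_freq=table(positives),
        neg_freq=table(negatives),
        pseudocount=pseudocount,
        gap_value_pos=gap_pos,
        gap_value_neg=gap_neg,
    )


@dataclass(frozen=True)
class EncodingScheme:
    """A named, ordered composition of encoding blocks over a fixed span."""

    name: str
    blocks: tuple[str, ...]
    span: tuple[int, int]

    @classmethod
    def from_name(cls, name: str, span: tuple[int, int]) -> "EncodingScheme":
        if name.upper() == "ALL":
            blocks = BLOCK_ORDER
        else:
            tokens = [t.strip().upper() for t in name.split("+")]
            bad = [t for t in tokens if t not in BLOCK_ORDER]
            if bad:
                raise EncodingError(f"unknown encoding blocks: {bad}")
            # canonical order regardless of how the name lists them
            blocks = tuple(b for b in BLOCK_ORDER if b in tokens)
        return cls(name=name.upper(), blocks=blocks, span=span)

    @property
    def L(self) -> int:
        return self.span[0] + self.span[1]

    @property
    def vector_length(self) -> int:
        return sum(self.L * 20 if b == "BEAA" else self.L * 2 for b in self.blocks)

    @property
    def bpb_channels(self) -> list[str]:
        return [_BLOCK_CHANNEL[b] for b in self.blocks if b != "BEAA"]


@dataclass
class FeatureVector:
    values: np.ndarray
    descriptors: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.descriptors):
            raise EncodingError("values and descriptors must be parallel")
        if len(set(self.descriptors)) != len(self.descriptors):
            raise EncodingError("descriptors must be unique")


def encode_beaa(window: SiteWindow) -> FeatureVector:
    """One-hot (orthonormal) encoding of the window residues; gap/X → all zeros."""
    labels = subsite_labels(window.span)
    aa_index = {aa: i for i, aa in enumerate(AA_ALPHABET)}
    values = np.zeros(window.length * 20)
    descriptors = [f"BEAA:{lab}:{aa}" for lab in labels for aa in AA_ALPHABET]
    for i, sym in enumerate(window.residues):
        j = aa_index.get(sym)
        if j is not None:
            values[i * 20 + j] = 1.0
    return FeatureVector(values=values, descriptors=descriptors)


def encode_bpb(window: SiteWindow, profile: BiProfile) -> FeatureVector:
    """Bi-profile encoding: per position the (positive, negative) profile value
    of the observed symbol; all positive-half values precede all negative-half
    values.  Symbols outside the channel alphabet (terminal padding) encode to
    the profile's configured gap frequencies."""
    if window.span != profile.span:
        raise EncodingError(f"window span {window.span} != profile span {profile.span}")
    labels = subsite_labels(window.span)
    sym_index = {s: j for j, s in enumerate(profile.alphabet)}
    chars = _channel_string(window, profile.channel)
    pos_half = np.empty(window.length)
    neg_half = np.empty(window.length)
    for i, sym in enumerate(chars):
        j = sym_index.get(sym)
        if j is None:
            pos_half[i] = profile.gap_value_pos
            neg_half[i] = profile.gap_value_neg
        else:
            pos_half[i] = profile.pos_freq[i, j]
            neg_half[i] = profile.neg_freq[i, j]
    block = f"BPB{profile.channel}"
    descriptors = [f"{block}:{lab}:pos" for lab in labels] + [
        f"{block}:{lab}:neg" for lab in labels
    ]
    return FeatureVector(values=np.concatenate([pos_half, neg_half]), descriptors=descriptors)


def encode(
    window: SiteWindow,
    scheme: EncodingScheme,
    profiles: dict[str, BiProfile] | None = None,
) -> FeatureVector:
    """Encode a window under a scheme, concatenating blocks in canonical order."""
    profiles = profiles or {}
    parts: list[FeatureVector] = []
    for block in scheme.blocks:
        if block == "BEAA":
            parts.append(encode_beaa(window))
        else:
            channel = _BLOCK_CHANNEL[block]
            if channel not in profiles:
                raise EncodingError(f"scheme {scheme.name} requires a fitted {block} profile")
            parts.append(encode_bpb(window, profiles[channel]))
    values = np.concatenate([p.values for p in parts])
    descriptors = [d for p in parts for d in p.descriptors]
    assert len(values) == scheme.vector_length
    return FeatureVector(values=values, descriptors=descriptors)


def encode_windows(
    windows: list[SiteWindow],
    scheme: EncodingScheme,
    profiles: dict[str, BiProfile] | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Encode many windows into a design matrix plus the shared descriptor list."""
    if not windows:
        raise EncodingError("no windows to encode")
    first = encode(windows[0], scheme, profiles)
    X = np.empty((len(windows), len(first.values)))
    X[0] = first.values
    for k, w in enumerate(windows[1:], start=1):
        X[k] = encode(w, scheme, profiles).values
    return X, first.descriptors


def fit_profiles(
    windows: list[SiteWindow],
    scheme: EncodingScheme,
    pseudocount: float = 1.0,
) -> dict[str, BiProfile]:
    """Fit every bi-profile the scheme needs from labelled training windows."""
    positives = [w for w in windows if w.is_positive]
    negatives = [w for w in windows if not w.is_positive]
    return {
        ch: fit_biprofile(positives, negatives, ch, pseudocount=pseudocount)
        for ch in scheme.bpb_channels
    }


def descriptor_group(descriptor: str) -> str:
    """Map a descriptor label to its feature-descriptor group.

    BEAA descriptors group per subsite (``BEAA:P1`` etc.); each bi-profile
    block is a single group, so the ALL scheme over P8–P8' partitions into
    16 + 4 = 20 groups.
    """
    parts = descriptor.split(":")
    if parts[0] == "BEAA":
        return f"BEAA:{parts[1]}"
    return parts[0]
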