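"""Feature encodings: positional weighted matrix, composition, ASA, SS.

The positional weighted matrix (PWM) is built from the non-homologous
positive fragments of the *training* data only: entry (p, s) is the fraction
of training fragments carrying symbol s at window offset p, over the
21-symbol alphabet (20 amino acids + the terminal padding signal).  A
fragment is encoded against the PWM as the ``2n+1`` vector of per-position
frequencies looked up at its own symbols (unseen symbols encode to 0); a
flattened one-hot variant is available via ``pwm_encoding="onehot"``.

Amino-acid composition (AAC) is the 20-vector of residue frequencies in the
window, with padding and 'X' excluded from numerator and denominator.  ASA
windows pass through as [0, 1] values; secondary structure is one-hot per
position in the order (H, E, C), with pad encoded as 000.  All encodings lie
in [0, 1], so no further rescaling is applied before the SVM.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .sequence_data import ALPHABET21, AMINO_ACIDS, PAD, SiteFragment, UNKNOWN, WindowConfig
from .structure import ResidueProfile, SS_PAD, SS_STATES, profile_window

#: Canonical concatenation order of feature blocks.
FEATURE_ORDER = ("AA_PWM", "AAC", "ASA", "SS")

_SYMBOL_INDEX = {s: i for i, s in enumerate(ALPHABET21)}
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


@dataclass
class PositionalWeightMatrix:
    """Per-position symbol frequencies over the 21-symbol alphabet."""

    n: int
    freq: np.ndarray  # shape (2n+1, 21), rows = offsets -n..+n

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, dtype=float)
        if self.freq.shape != (2 * self.n + 1, 21):
            raise ValueError(
                f"PWM shape {self.freq.shape} does not match n={self.n}"
            )

    @property
    def window_length(self) -> int:
        return 2 * self.n + 1

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("position\t" + "\t".join(ALPHABET21) + "\n")
            for p, row in zip(range(-self.n, self.n + 1), self.freq):
                fh.write(str(p) + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")

    @classmethod
    def from_tsv(cls, path) -> "PositionalWeightMatrix":
        rows = []
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header[1:] != list(ALPHABET21):
                raise ValueError(f"{path}: unexpected PWM column header")
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) == 22:
                    rows.append([float(v) for v in parts[1:]])
        n = (len(rows) - 1) // 2
        return cls(n, np.array(rows))


def build_pwm(
    positive_fragments: Sequence[SiteFragment], cfg: WindowConfig
) -> PositionalWeightMatrix:
    """Occurrence-frequency PWM from positive fragments; no pseudocounts.

    'X' symbols are not part of the 21-letter alphabet and contribute
    nothing (the corresponding row mass is simply missing for them).
    """
    if not positive_fragments:
        raise ValueError("cannot build a PWM from zero fragments")
    length = cfg.window_length
    counts = np.zeros((length, 21))
    for frag in positive_fragments:
        if len(frag.window) != length:
            raise ValueError(
                f"fragment length {len(frag.window)} does not match window "
                f"length {length}"
            )
        for p, sym in enumerate(frag.window):
            idx = _SYMBOL_INDEX.get(sym)
            if idx is not None:
                counts[p, idx] += 1
    return PositionalWeightMatrix(cfg.n, counts / len(positive_fragments))


def encode_pwm(fragment: SiteFragment, pwm: PositionalWeightMatrix) -> np.ndarray:
    """Per-position frequency lookup: element p = freq[p][fragment[p]]."""
    if len(fragment.window) != pwm.window_length:
        raise ValueError("fragment length does not match PWM")
    out = np.zeros(pwm.window_length)
    for p, sym in enumerate(fragment.window):
        if sym == UNKNOWN:
            continue
        idx = _SYMBOL_INDEX.get(sym)
        if idx is None:
            raise ValueError(f"symbol '{sym}' outside the fragment alphabet")
        out[p] = pwm.freq[p, idx]
    return out


def encode_pwm_onehot(
    fragment: SiteFragment, pwm: PositionalWeightMatrix
) -> np.ndarray:
    """Flattened (2n+1) x 21 per-position one-hot of the fragment symbols."""
    if len(fragment.window) != pwm.window_length:
        raise ValueError("fragment length does not match PWM")
    out = np.zeros((pwm.window_length, 21))
    for p, sym in enumerate(fragment.window):
        if sym == UNKNOWN:
            continue
        idx = _SYMBOL_INDEX.get(sym)
        if idx is None:
            raise ValueError(f"symbol '{sym}' outside the fragment alphabet")
        out[p, idx] = 1.0
    return out.ravel()


def encode_aac(fragment: SiteFragment) -> np.ndarray:
    """20-vector of residue frequencies; padding and 'X' excluded entirely."""
    counts = np.zeros(20)
    total = 0
    for sym in fragment.window:
        if sym in (PAD, UNKNOWN):
            continue
        counts[_AA_INDEX[sym]] += 1
        total += 1
    if total == 0:
        raise ValueError("fragment has no countable residues")
    return counts / total


def encode_asa(asa_window: Sequence[float]) -> np.ndarray:
    """Identity pass-through of normalized ASA values with a range check."""
    arr = np.asarray(asa_window, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("normalized ASA values must lie in [0, 1]")
    return arr


def encode_ss(ss_window: Sequence[str]) -> np.ndarray:
    """Per-position 3-bit one-hot (H, E, C); pad positions encode as 000."""
    out = np.zeros((len(ss_window), 3))
    for p, state in enumerate(ss_window):
        if state == SS_PAD:
            continue
        if state not in SS_STATES:
            raise ValueError(f"unknown secondary-structure state '{state}'")
        out[p, SS_STATES.index(state)] = 1.0
    return out.ravel()


def feature_lengths(
    selection: Sequence[str], cfg: WindowConfig, pwm_encoding: str = "lookup"
) -> list[tuple[str, int]]:
    """Ordered (block name, span) schema for a feature selection."""
    unknown = set(selection) - set(FEATURE_ORDER)
    if unknown:
        raise ValueError(f"unknown feature blocks {sorted(unknown)}")
    if not selection:
        raise ValueError("feature selection is empty")
    w = cfg.window_length
    spans = {
        "AA_PWM": w if pwm_encoding == "lookup" else w * 21,
        "AAC": 20,
        "ASA": w,
        "SS": 3 * w,
    }
    return [(name, spans[name]) for name in FEATURE_ORDER if name in selection]


@dataclass
class FeatureVector:
    """Concatenated numeric encoding of a fragment plus its block schema."""

    values: np.ndarray
    schema: list[tuple[str, int]]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != sum(span for _, span in self.schema):
            raise ValueError("feature vector length does not match schema")


def concat_features(
    fragment: SiteFragment,
    pwm: PositionalWeightMatrix | None,
    profile: ResidueProfile | None,
    selection: Sequence[str],
    cfg: WindowConfig | None = None,
    pwm_encoding: str = "lookup",
) -> FeatureVector:
    """Concatenate the selected blocks in the fixed order PWM, AAC, ASA, SS."""
    if cfg is None:
        cfg = WindowConfig(fragment.n)
    selected = set(selection)
    schema = feature_lengths(sorted(selected), cfg, pwm_encoding)
    needs_profile = bool(selected & {"ASA", "SS"})
    if needs_profile and profile is None:
        raise ValueError("ASA/SS features require a residue profile")
    if "AA_PWM" in selected and pwm is None:
        raise ValueError("AA_PWM features require a positional weighted matrix")
    asa_win = ss_win = None
    if needs_profile:
        asa_win, ss_win = profile_window(profile, fragment.center, cfg)
    blocks: list[np.ndarray] = []
    for name, _ in schema:
        if name == "AA_PWM":
            enc = encode_pwm if pwm_encoding == "lookup" else encode_pwm_onehot
            blocks.append(enc(fragment, pwm))
        elif name == "AAC":
            blocks.append(encode_aac(fragment))
        elif name == "ASA":
            blocks.append(encode_asa(asa_win))
        elif name == "SS":
            blocks.append(encode_ss(ss_win))
    return FeatureVector(np.concatenate(blocks), schema)


def encode_dataset(
    fragments: Sequence[SiteFragment],
    profiles: Mapping[str, ResidueProfile] | None,
    selection: Sequence[str],
    pwm: PositionalWeightMatrix | None,
    cfg: WindowConfig,
    pwm_encoding: str = "lookup",
) -> tuple[np.ndarray, np.ndarray, list[tuple[str, int]]]:
    """Feature matrix X, binary label vector y (1 = positive), and schema."""
    rows: list[np.ndarray] = []
    schema: list[tuple[str, int]] = feature_lengths(sorted(set(selection)), cfg, pwm_encoding)
    for frag in fragments:
        profile = None
        if profiles is not None and frag.protein_id in profiles:
            profile = profiles[frag.protein_id]
        elif set(selection) & {"ASA", "SS"}:
            raise ValueError(f"missing structure profile for {frag.protein_id}")
        fv = concat_features(frag, pwm, profile, selection, cfg, pwm_encoding)
        rows.append(fv.values)
    X = np.vstack(rows) if rows else np.empty((0, sum(s for _, s in schema)))
    y = np.array([1 if f.is_positive else 0 for f in fragments], dtype=int)
    return X, y, schema
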