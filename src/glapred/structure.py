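"""Per-residue structure profiles: solvent accessibility and secondary structure.

ASA (solvent-accessible surface area) arrives as a percent per residue in a
neutral 3-column TSV; secondary structure arrives as PSIPRED VFORMAT (.ss2)
with the 3-state alphabet H (helix), E (sheet), C (coil).  Profiles are
aligned to fragment windows; positions beyond a terminus get ASA 0 and the
``pad`` state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sequence_data import WindowConfig

SS_STATES = ("H", "E", "C")
SS_PAD = "pad"


class ProfileError(ValueError):
    """Raised for malformed or inconsistent structure inputs."""


@dataclass
class ResidueProfile:
    """ASA percent and 3-state secondary structure for one protein."""

    protein_id: str
    asa_percent: np.ndarray  # shape (L,), values in [0, 100]
    ss: str  # length-L string over HEC

    def __post_init__(self) -> None:
        self.asa_percent = np.asarray(self.asa_percent, dtype=float)
        if self.asa_percent.ndim != 1:
            raise ProfileError(f"{self.protein_id}: ASA must be a 1-D list")
        if len(self.asa_percent) != len(self.ss):
            raise ProfileError(
                f"{self.protein_id}: ASA length {len(self.asa_percent)} != "
                f"SS length {len(self.ss)}"
            )
        if np.any((self.asa_percent < 0) | (self.asa_percent > 100)):
            raise ProfileError(f"{self.protein_id}: ASA values outside [0, 100]")
        bad = set(self.ss) - set(SS_STATES)
        if bad:
            raise ProfileError(f"{self.protein_id}: invalid SS states {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.ss)


def read_asa_table(path) -> dict[str, np.ndarray]:
    """Read per-residue ASA percentages from TSV rows (id, 1-based pos, percent).

    Positions of each protein must form a dense 1..L run; a gap raises a
    completeness error, a value outside [0, 100] a range error.
    """
    values: dict[str, dict[int, float]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ProfileError(f"{path}:{lineno}: expected 3 fields")
            pid, pos, asa = parts[0], int(parts[1]), float(parts[2])
            if not 0 <= asa <= 100:
                raise ProfileError(
                    f"{path}:{lineno}: ASA {asa} outside [0, 100] for {pid}"
                )
            values.setdefault(pid, {})[pos] = asa
    out: dict[str, np.ndarray] = {}
    for pid, by_pos in values.items():
        length = max(by_pos)
        missing = [p for p in range(1, length + 1) if p not in by_pos]
        if missing:
            raise ProfileError(
                f"{path}: {pid} missing ASA for positions {missing[:5]}"
            )
        out[pid] = np.array([by_pos[p] for p in range(1, length + 1)])
    return out


def read_psipred_ss2(path, sequence: str | None = None) -> str:
    """Extract the state-letter column from a PSIPRED VFORMAT .ss2 file.

    If *sequence* is given, the residue column is checked against it;
    a mismatch raises a consistency error.
    """
    states: list[str] = []
    residues: list[str] = []
    with open(path) as fh:
        for line in fh:
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            parts = stripped.split()
            if len(parts) < 3:
                raise ProfileError(f"{path}: malformed .ss2 row: {stripped!r}")
            residues.append(parts[1])
            state = parts[2]
            if state not in SS_STATES:
                raise ProfileError(f"{path}: unknown SS state '{state}'")
            states.append(state)
    if not states:
        raise ProfileError(f"{path}: .ss2 file has no body rows")
    if sequence is not None:
        if len(residues) != len(sequence):
            raise ProfileError(
                f"{path}: {len(residues)} .ss2 rows but sequence length "
                f"{len(sequence)}"
            )
        for i, (r, s) in enumerate(zip(residues, sequence), 1):
            if r != s:
                raise ProfileError(
                    f"{path}: residue '{r}' at position {i} does not match "
                    f"sequence residue '{s}'"
                )
    return "".join(states)


def build_profile(
    protein_id: str, sequence: str, asa_percent: np.ndarray, ss: str
) -> ResidueProfile:
    """Assemble and length-check a profile against its protein sequence."""
    if len(asa_percent) != len(sequence) or len(ss) != len(sequence):
        raise ProfileError(
            f"{protein_id}: profile lengths (ASA {len(asa_percent)}, SS "
            f"{len(ss)}) do not match sequence length {len(sequence)}"
        )
    return ResidueProfile(protein_id, asa_percent, ss)


def profile_window(
    profile: ResidueProfile, center: int, cfg: WindowConfig
) -> tuple[np.ndarray, list[str]]:
    """Window the profile around *center* (1-based).

    Returns the ASA values rescaled from percent to [0, 1] and the SS state
    list; positions beyond the termini contribute ASA 0 and state ``pad``.
    """
    if not 1 <= center <= len(profile):
        raise ValueError(f"center {center} outside profile of length {len(profile)}")
    n = cfg.n
    asa = np.zeros(2 * n + 1)
    ss: list[str] = [SS_PAD] * (2 * n + 1)
    for j, pos in enumerate(range(center - n, center + n + 1)):
        if 1 <= pos <= len(profile):
            asa[j] = profile.asa_percent[pos - 1] / 100.0
            ss[j] = profile.ss[pos - 1]
    return asa, ss
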