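"""Synthetic benchmark generator for the carboxylation-site pipeline.

The generator emulates the statistical structure observed around real Gla
sites so every pipeline stage is testable without external downloads:

* Glu enrichment in positive flanks at offsets -7, -6, -4, -3, -1, +1, +3,
  +4, +6, +7 and depletion at -2/+2;
* slight arginine enrichment at -7, -5, -4, -1, +3;
* elevated solvent accessibility at the carboxylated Glu (mean 37.8%), with
  dips at the Glu-depleted offsets -2/+2 and an elevated -7..-4 shoulder;
* coil/helix-dominated secondary structure at the site (C 53%, H 42.6%,
  E 4.4%).

Each protein carries a fixed number of planted positive and negative
15-mer windows; glutamates that arise incidentally in window flanks or in
the background sequence become additional negative sites at extraction
time, which keeps the positive:negative ratio near the 302:567 proportions
of the curated training data.  Residues are drawn independently, so the
output has no homologous families (an optional duplicated-protein injection
exercises the redundancy-removal stage) and no realistic secondary-structure
runs.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .evaluation import ConfusionCounts
from .sequence_data import AMINO_ACIDS, ProteinRecord, WindowConfig
from .structure import ResidueProfile, SS_STATES

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
_E = _AA_INDEX["E"]
_R = _AA_INDEX["R"]

#: Offsets with Glu enrichment in positive windows.
GLU_ENRICHED_OFFSETS = (-7, -6, -4, -3, -1, 1, 3, 4, 6, 7)
#: Offsets with Glu depletion in positive windows.
GLU_DEPLETED_OFFSETS = (-2, 2)
#: Offsets with arginine enrichment in positive windows.
ARG_ENRICHED_OFFSETS = (-7, -5, -4, -1, 3)


def _background(e_prob: float) -> np.ndarray:
    """Near-uniform residue distribution with a controlled Glu probability."""
    probs = np.full(20, (1.0 - e_prob) / 19.0)
    probs[_E] = e_prob
    return probs


def _set_prob(row: np.ndarray, idx: int, value: float) -> np.ndarray:
    """Fix one residue probability, rescaling the rest proportionally."""
    out = row.copy()
    rest = 1.0 - out[idx]
    out[idx] = value
    mask = np.arange(20) != idx
    out[mask] *= (1.0 - value) / rest
    return out


def positive_window_probs(
    n: int = 7,
    flank_e_prob: float = 0.02,
    enriched_e_prob: float = 0.12,
    depleted_e_prob: float = 0.005,
    enriched_r_prob: float = 0.15,
) -> np.ndarray:
    """Per-offset residue distributions for positive windows, shape (2n+1, 20).

    The central row is a point mass on Glu.
    """
    probs = np.tile(_background(flank_e_prob), (2 * n + 1, 1))
    for off in GLU_ENRICHED_OFFSETS:
        if abs(off) <= n:
            probs[off + n] = _set_prob(probs[off + n], _E, enriched_e_prob)
    for off in GLU_DEPLETED_OFFSETS:
        if abs(off) <= n:
            probs[off + n] = _set_prob(probs[off + n], _E, depleted_e_prob)
    for off in ARG_ENRICHED_OFFSETS:
        if abs(off) <= n:
            probs[off + n] = _set_prob(probs[off + n], _R, enriched_r_prob)
    center = np.zeros(20)
    center[_E] = 1.0
    probs[n] = center
    return probs


def negative_window_probs(n: int = 7, flank_e_prob: float = 0.04) -> np.ndarray:
    """Background flanks around a central (non-carboxylated) Glu."""
    probs = np.tile(_background(flank_e_prob), (2 * n + 1, 1))
    center = np.zeros(20)
    center[_E] = 1.0
    probs[n] = center
    return probs


def positive_asa_means(n: int = 7) -> np.ndarray:
    """Mean ASA percent per offset for positive windows (center 37.8)."""
    means = np.full(2 * n + 1, 30.0)
    for off in range(-n, n + 1):
        if -7 <= off <= -4:
            means[off + n] = 35.0
    for off in GLU_DEPLETED_OFFSETS:
        if abs(off) <= n:
            means[off + n] = 22.0
    means[n] = 37.8
    return means


@dataclass
class GeneratorSpec:
    """Parameters of the synthetic benchmark.

    All probability vectors must sum to 1; a fixed seed makes the output
    byte-identical across runs.
    """

    n_proteins: int = 80
    length_range: tuple[int, int] = (200, 600)
    positives_per_protein: int = 4
    planted_negatives_per_protein: int = 2
    window_n: int = 7
    positive_probs: np.ndarray = field(default_factory=positive_window_probs)
    negative_probs: np.ndarray = field(default_factory=negative_window_probs)
    background_probs: np.ndarray = field(default_factory=lambda: _background(0.005))
    positive_asa_mean: np.ndarray = field(default_factory=positive_asa_means)
    negative_asa_mean: float = 24.0
    background_asa_mean: float = 25.0
    asa_sd: float = 8.0
    # SS probabilities in (H, E, C) order.
    positive_center_ss: tuple[float, float, float] = (0.426, 0.044, 0.53)
    positive_flank_ss: tuple[float, float, float] = (0.40, 0.10, 0.50)
    negative_ss: tuple[float, float, float] = (0.28, 0.27, 0.45)
    background_ss: tuple[float, float, float] = (0.33, 0.27, 0.40)
    duplicated_proteins: int = 0  # optional homologous-family injection
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("positive_probs", "negative_probs"):
            mat = np.asarray(getattr(self, name), dtype=float)
            if mat.shape != (2 * self.window_n + 1, 20):
                raise ValueError(f"{name} must have shape (2n+1, 20)")
            if not np.allclose(mat.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError(f"{name} rows must sum to 1")
            if np.any(mat < 0):
                raise ValueError(f"{name} has negative probabilities")
            setattr(self, name, mat)
        for name in (
            "background_probs",
            "positive_center_ss",
            "positive_flank_ss",
            "negative_ss",
            "background_ss",
        ):
            vec = np.asarray(getattr(self, name), dtype=float)
            if not np.isclose(vec.sum(), 1.0, atol=1e-9) or np.any(vec < 0):
                raise ValueError(f"{name} must be a probability vector")
        if self.length_range[0] < 4 * (2 * self.window_n + 1):
            raise ValueError("proteins too short for the requested site count")


@dataclass
class SyntheticDataset:
    """In-memory view of a generated benchmark, plus file export."""

    records: list[ProteinRecord]
    profiles: dict[str, ResidueProfile]
    truth: pd.DataFrame  # columns: protein_id, position, label

    def write(self, outdir) -> dict[str, str]:
        os.makedirs(outdir, exist_ok=True)
        ss2_dir = os.path.join(outdir, "ss2")
        os.makedirs(ss2_dir, exist_ok=True)
        paths = {
            "fasta": os.path.join(outdir, "sequences.fasta"),
            "sites": os.path.join(outdir, "sites.tsv"),
            "asa": os.path.join(outdir, "asa.tsv"),
            "ss2_dir": ss2_dir,
            "truth": os.path.join(outdir, "truth.tsv"),
        }
        with open(paths["fasta"], "w") as fh:
            for rec in self.records:
                fh.write(f">{rec.id}\n")
                for i in range(0, len(rec.sequence), 60):
                    fh.write(rec.sequence[i : i + 60] + "\n")
        with open(paths["sites"], "w") as fh:
            for rec in self.records:
                for pos in rec.carboxylation_positions:
                    fh.write(f"{rec.id}\t{pos}\n")
        with open(paths["asa"], "w") as fh:
            for rec in self.records:
                prof = self.profiles[rec.id]
                for pos, asa in enumerate(prof.asa_percent, 1):
                    fh.write(f"{rec.id}\t{pos}\t{asa:.2f}\n")
        for rec in self.records:
            prof = self.profiles[rec.id]
            with open(os.path.join(ss2_dir, f"{rec.id}.ss2"), "w") as fh:
                fh.write("# PSIPRED VFORMAT (synthetic)\n\n")
                for pos, (aa, state) in enumerate(zip(rec.sequence, prof.ss), 1):
                    conf = {"C": 0, "H": 1, "E": 2}[state]
                    scores = [0.0, 0.0, 0.0]
                    scores[conf] = 1.0
                    fh.write(
                        f"{pos:4d} {aa} {state}  {scores[0]:.3f} "
                        f"{scores[1]:.3f} {scores[2]:.3f}\n"
                    )
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        return paths


def _pick_site_centers(
    rng: np.random.Generator, length: int, n_sites: int, n: int
) -> list[int]:
    """Non-overlapping window centers (1-based), min spacing 2n+1."""
    candidates = list(range(n + 1, length - n + 1))
    rng.shuffle(candidates)
    chosen: list[int] = []
    for c in candidates:
        if all(abs(c - prev) > 2 * n for prev in chosen):
            chosen.append(c)
            if len(chosen) == n_sites:
                break
    if len(chosen) < n_sites:
        raise ValueError("protein too short to place the requested sites")
    return chosen


def _draw_ss(rng: np.random.Generator, probs: Sequence[float]) -> str:
    return SS_STATES[rng.choice(3, p=np.asarray(probs))]


def generate(spec: GeneratorSpec) -> SyntheticDataset:
    """Draw a complete mutually consistent benchmark from *spec*.

    Output: FASTA-ready records with positive annotations, ASA/SS profiles,
    and a truth table labelling every Glu residue.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.window_n
    aa = np.array(list(AMINO_ACIDS))
    records: list[ProteinRecord] = []
    profiles: dict[str, ResidueProfile] = {}
    truth_rows: list[dict] = []

    for p_idx in range(spec.n_proteins):
        pid = f"SYN{p_idx:04d}"
        length = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
        seq = rng.choice(20, size=length, p=spec.background_probs)
        asa = rng.normal(spec.background_asa_mean, spec.asa_sd, size=length)
        ss = [
            _draw_ss(rng, spec.background_ss) for _ in range(length)
        ]
        n_sites = spec.positives_per_protein + spec.planted_negatives_per_protein
        centers = _pick_site_centers(rng, length, n_sites, n)
        positive_centers = sorted(centers[: spec.positives_per_protein])
        negative_centers = sorted(centers[spec.positives_per_protein :])
        for center in positive_centers:
            for j in range(2 * n + 1):
                pos = center - n + j
                seq[pos - 1] = rng.choice(20, p=spec.positive_probs[j])
                asa[pos - 1] = rng.normal(spec.positive_asa_mean[j], spec.asa_sd)
                probs = (
                    spec.positive_center_ss if j == n else spec.positive_flank_ss
                )
                ss[pos - 1] = _draw_ss(rng, probs)
        for center in negative_centers:
            for j in range(2 * n + 1):
                pos = center - n + j
                seq[pos - 1] = rng.choice(20, p=spec.negative_probs[j])
                asa[pos - 1] = rng.normal(spec.negative_asa_mean, spec.asa_sd)
                ss[pos - 1] = _draw_ss(rng, spec.negative_ss)
        sequence = "".join(aa[seq])
        record = ProteinRecord(pid, sequence, positive_centers)
        records.append(record)
        profiles[pid] = ResidueProfile(
            pid, np.clip(asa, 0.0, 100.0), "".join(ss)
        )
        pos_set = set(positive_centers)
        for i, residue in enumerate(sequence, 1):
            if residue == "E":
                truth_rows.append(
                    {
                        "protein_id": pid,
                        "position": i,
                        "label": "positive" if i in pos_set else "negative",
                    }
                )

    for d in range(spec.duplicated_proteins):
        src = records[d % max(1, len(records))]
        pid = f"{src.id}DUP"
        records.append(
            ProteinRecord(pid, src.sequence, list(src.carboxylation_positions))
        )
        prof = profiles[src.id]
        profiles[pid] = ResidueProfile(pid, prof.asa_percent.copy(), prof.ss)
        for i, residue in enumerate(src.sequence, 1):
            if residue == "E":
                truth_rows.append(
                    {
                        "protein_id": pid,
                        "position": i,
                        "label": "positive"
                        if i in set(src.carboxylation_positions)
                        else "negative",
                    }
                )

    truth = pd.DataFrame(
        truth_rows, columns=["protein_id", "position", "label"]
    )
    return SyntheticDataset(records, profiles, truth)


def truth_eval(predictions: pd.DataFrame, truth: pd.DataFrame) -> ConfusionCounts:
    """Score (protein_id, position, label) predictions against the truth table.

    Every prediction must match a truth row; an unmatched prediction raises.
    """
    truth_map = {
        (row.protein_id, int(row.position)): row.label
        for row in truth.itertuples()
    }
    counts = ConfusionCounts()
    tp = fp = tn = fn = 0
    for row in predictions.itertuples():
        key = (row.protein_id, int(row.position))
        if key not in truth_map:
            raise ValueError(f"prediction at {key} has no matching truth row")
        actual_pos = truth_map[key] == "positive"
        predicted_pos = row.label == "positive"
        if actual_pos and predicted_pos:
            tp += 1
        elif actual_pos:
            fn += 1
        elif predicted_pos:
            fp += 1
        else:
            tn += 1
    return counts + ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)
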