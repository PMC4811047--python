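"""Fixed-length window extraction around candidate phosphosites and
redundancy removal by pairwise global-alignment identity.

Windows overhanging a protein terminus are padded with 'X' on the short
side so no annotated site is lost; every encoder defines an explicit
placeholder rule (see :mod:`phosforest.features`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence, TypeVar

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices

from .io import ProteinRecord, SiteAnnotation

logger = logging.getLogger(__name__)

T = TypeVar("T")


@dataclass(frozen=True)
class SequenceWindow:
    """Odd-length residue window centered on an S/T/Y with a binary label."""

    protein_id: str
    center_position: int  # 1-based
    center_residue: str
    residues: str
    label: str

    def __post_init__(self):
        w = len(self.residues)
        if w < 3 or w % 2 == 0:
            raise ValueError(f"window length must be odd and >= 3, got {w}")
        mid = (w - 1) // 2
        if self.residues[mid] != self.center_residue:
            raise ValueError(
                f"window middle {self.residues[mid]!r} != center residue "
                f"{self.center_residue!r}"
            )


def window_at(sequence: str, position: int, w: int) -> str:
    """The w-length window centered at 1-based ``position``, 'X'-padded."""
    if w < 3 or w % 2 == 0:
        raise ValueError(f"window size must be odd and >= 3, got {w}")
    half = (w - 1) // 2
    lo = position - 1 - half
    hi = position - 1 + half + 1
    pad_left = max(0, -lo)
    pad_right = max(0, hi - len(sequence))
    return "X" * pad_left + sequence[max(0, lo) : min(len(sequence), hi)] + "X" * pad_right


def extract_windows(
    proteins: Sequence[ProteinRecord],
    annotations: Sequence[SiteAnnotation],
    w: int,
    residue_filter: Iterable[str] = frozenset("STY"),
    include_candidate_negatives: bool = False,
) -> list[SequenceWindow]:
    """One window per annotated site whose residue is in the filter.

    With ``include_candidate_negatives`` every unannotated S/T/Y of a
    filtered residue type is also emitted as a candidate negative.
    """
    residue_filter = frozenset(residue_filter)
    by_id = {p.id: p for p in proteins}
    out: list[SequenceWindow] = []
    annotated: set[tuple[str, int]] = set()
    for ann in annotations:
        annotated.add((ann.protein_id, ann.position))
        if ann.residue not in residue_filter:
            continue
        seq = by_id[ann.protein_id].sequence
        out.append(
            SequenceWindow(
                ann.protein_id,
                ann.position,
                ann.residue,
                window_at(seq, ann.position, w),
                ann.label,
            )
        )
    if include_candidate_negatives:
        for prot in proteins:
            for pos, ch in enumerate(prot.sequence, start=1):
                if ch in residue_filter and (prot.id, pos) not in annotated:
                    out.append(
                        SequenceWindow(prot.id, pos, ch, window_at(prot.sequence, pos, w), "negative")
                    )
    return out


def _make_aligner(gap_open: float, gap_extend: float) -> PairwiseAligner:
    aligner = PairwiseAligner(
        mode="global",
        substitution_matrix=substitution_matrices.load("BLOSUM62"),
        open_gap_score=-abs(gap_open),
        extend_gap_score=-abs(gap_extend),
    )
    return aligner


def percent_identity(a: str, b: str, aligner: PairwiseAligner | None = None) -> float:
    """Global-alignment percent identity: matches / alignment length * 100."""
    if aligner is None:
        aligner = _make_aligner(10.0, 0.5)
    aln = aligner.align(a, b)[0]
    counts = aln.counts()
    return 100.0 * counts.identities / aln.length


def remove_redundant(
    items: Sequence[T],
    identity_threshold: float = 20.0,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
    key: Callable[[T], str] | None = None,
) -> tuple[list[T], list[tuple[int, int, float]]]:
    """Greedy single-pass redundancy filter in input order.

    An item is dropped iff its pairwise global-alignment percent identity
    (Needleman-Wunsch, BLOSUM62, the given gap penalties) to any
    already-retained item exceeds ``identity_threshold``. Returns
    (retained, drop_log) where the log holds
    (dropped_input_index, matched_input_index, identity_percent).
    """
    if not 0 < identity_threshold <= 100:
        raise ValueError(f"identity threshold must be in (0, 100], got {identity_threshold}")
    if not items:
        raise ValueError("remove_redundant needs a nonempty input")
    if key is None:
        key = lambda it: it.residues if hasattr(it, "residues") else (
            it.sequence if hasattr(it, "sequence") else str(it)
        )
    aligner = _make_aligner(gap_open, gap_extend)
    retained: list[T] = []
    retained_idx: list[int] = []
    retained_seqs: list[str] = []
    dropped: list[tuple[int, int, float]] = []
    for i, item in enumerate(items):
        seq = key(item)
        hit = None
        for j, other in enumerate(retained_seqs):
            ident = percent_identity(seq, other, aligner)
            if ident > identity_threshold:
                hit = (retained_idx[j], ident)
                break
        if hit is None:
            retained.append(item)
            retained_idx.append(i)
            retained_seqs.append(seq)
        else:
            dropped.append((i, hit[0], hit[1]))
    logger.info(
        "remove_redundant: kept %d of %d (threshold %.1f%%)",
        len(retained), len(items), identity_threshold,
    )
    return retained, dropped


def balance_negatives(
    positives: Sequence[T], negatives: Sequence[T], seed: int
) -> list[T]:
    """Sample exactly len(positives) negatives without replacement (seeded)."""
    if len(negatives) < len(positives):
        raise ValueError(
            f"{len(negatives)} negatives < {len(positives)} positives; "
            "disable balancing or supply more negatives"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(negatives), size=len(positives), replace=False)
    return [negatives[i] for i in sorted(idx)]


def write_windows(windows: Iterable[SequenceWindow], path) -> None:
    """Windows as TSV (protein_id, center_position, residue, window, label)."""
    with open(path, "w") as fh:
        fh.write("protein_id\tcenter_position\tresidue\twindow\tlabel\n")
        for win in windows:
            fh.write(
                f"{win.protein_id}\t{win.center_position}\t{win.center_residue}"
                f"\t{win.residues}\t{win.label}\n"
            )


def read_windows(path) -> list[SequenceWindow]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    return [
        SequenceWindow(r.protein_id, int(r.center_position), r.residue, r.window, r.label)
        for r in df.itertuples(index=False)
    ]
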