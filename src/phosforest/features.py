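"""Window descriptor encoders.

Each candidate phosphosite window (odd length ``w``, centered on S/T/Y)
is encoded into one fixed-length numeric vector built from ten descriptor
families, concatenated in a fixed order:

====== ======================================== ==========
family meaning                                  length (w)
====== ======================================== ==========
H      Shannon entropy of the window            1
RE     relative entropy vs the uniform 1/w      1
IG     information gain, H - RE                 1
ASA    per-residue solvent accessibility        w
OP     10 overlapping physicochemical classes   10*w
ACH    mean Eisenberg hydrophobicity of nested
       centered subwindows (sizes 3,5,...,w)    (w-1)/2
SF     one-hot residue identity                 20*w
CTD    composition/transition/distribution
       over 3 groups x 7 properties             147
SOCN   sequence-order coupling numbers, lags
       1..30 under two distance matrices        60
QSO    quasi-sequence-order descriptors         100
====== ======================================== ==========

At w = 9 the total is 593. Feature names carry the 1-based global index
("QSO_569"), so importance tables are directly comparable across runs.

Placeholder rule ('X', used for terminal padding and sanitized letters):
excluded from all probability/count denominators (H, RE, IG, CTD),
contributes 0 to scale sums and distances (ACH, ASA fallback, SOCN, QSO),
and encodes as all-zero bits (OP, SF).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import numpy as np

from ._scales import (
    AMINO_ACIDS,
    CTD_CODES,
    CTD_PROPERTY_NAMES,
    DISTANCE_MATRICES,
    EISENBERG_VEC,
    N_AA,
    OP_BITS,
    ONE_HOT,
    X_INDEX,
    encode_indices,
)

if TYPE_CHECKING:  # pragma: no cover
    from .io import AsaProfile
    from .windows import SequenceWindow

SCHEMA_VERSION = "1.0"

SOCN_MAXLAG = 30
QSO_MAXLAG = 40
QSO_WEIGHT = 0.1

CTD_LENGTH = 147  # 7 properties x (3 composition + 3 transition + 15 distribution)
SOCN_LENGTH = 2 * SOCN_MAXLAG
QSO_LENGTH = N_AA + 2 * QSO_MAXLAG

FAMILY_ORDER = ("H", "RE", "IG", "ASA", "OP", "ACH", "SF", "CTD", "SOCN", "QSO")


def family_lengths(window_size: int) -> dict[str, int]:
    """Descriptor-block lengths for a given window size."""
    w = window_size
    return {
        "H": 1,
        "RE": 1,
        "IG": 1,
        "ASA": w,
        "OP": 10 * w,
        "ACH": (w - 1) // 2,
        "SF": 20 * w,
        "CTD": CTD_LENGTH,
        "SOCN": SOCN_LENGTH,
        "QSO": QSO_LENGTH,
    }


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered registry of descriptor blocks for one window size.

    ``blocks`` holds (family, start, stop) with 1-based inclusive global
    indices; ``names`` holds one stable string per position.
    """

    window_size: int
    blocks: tuple[tuple[str, int, int], ...]
    names: tuple[str, ...]
    version: str = SCHEMA_VERSION

    @property
    def total_length(self) -> int:
        return self.blocks[-1][2]

    @classmethod
    def for_window(cls, window_size: int) -> "FeatureSchema":
        if window_size < 3 or window_size % 2 == 0:
            raise ValueError(f"window size must be odd and >= 3, got {window_size}")
        lengths = family_lengths(window_size)
        blocks = []
        names: list[str] = []
        start = 1
        for fam in FAMILY_ORDER:
            stop = start + lengths[fam] - 1
            blocks.append((fam, start, stop))
            names.extend(f"{fam}_{i}" for i in range(start, stop + 1))
            start = stop + 1
        return cls(window_size=window_size, blocks=tuple(blocks), names=tuple(names))

    def block_range(self, family: str) -> tuple[int, int]:
        """1-based inclusive (start, stop) of a family's block."""
        for fam, start, stop in self.blocks:
            if fam == family:
                return start, stop
        raise KeyError(family)

    def block_slice(self, family: str) -> slice:
        """0-based slice selecting a family's columns."""
        start, stop = self.block_range(family)
        return slice(start - 1, stop)

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "window_size": self.window_size,
            "blocks": [list(b) for b in self.blocks],
            "names": list(self.names),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: Mapping) -> "FeatureSchema":
        return cls(
            window_size=int(d["window_size"]),
            blocks=tuple(tuple(b) for b in d["blocks"]),
            names=tuple(d["names"]),
            version=str(d["version"]),
        )


@dataclass(frozen=True)
class FeatureVector:
    schema: FeatureSchema
    values: np.ndarray = field(repr=False)

    def __post_init__(self):
        if len(self.values) != self.schema.total_length:
            raise ValueError(
                f"vector length {len(self.values)} != schema length "
                f"{self.schema.total_length}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature vector contains non-finite values")


def _probabilities(window: str) -> tuple[np.ndarray, int]:
    """Residue probabilities over the effective (placeholder-free) length."""
    idx = encode_indices(window)
    idx = idx[idx != X_INDEX]
    eff = len(idx)
    counts = np.bincount(idx, minlength=N_AA).astype(float)
    return (counts / eff if eff else counts), eff


def shannon_entropy(window: str) -> float:
    """Window-wise Shannon entropy (bits) of the residue composition.

    0 for a single-residue-type window; log2(w) when all residues differ.
    An all-placeholder window is defined as 0 (with a warning).
    """
    p, eff = _probabilities(window)
    if eff == 0:
        warnings.warn("entropy of an all-placeholder window is defined as 0")
        return 0.0
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def relative_entropy(window: str, window_size: int | None = None) -> float:
    """Relative entropy of the composition against the uniform 1/w.

    The reference probability is 1/window_size (the configured window
    length, padding included), and zero-probability residues are skipped,
    mirroring how the descriptor is defined for fixed-length windows.
    """
    w = window_size if window_size is not None else len(window)
    p, eff = _probabilities(window)
    if eff == 0:
        return 0.0
    p0 = 1.0 / w
    nz = p[p > 0]
    return float((nz * np.log2(nz / p0)).sum())


def information_gain(window: str, window_size: int | None = None) -> float:
    """H - RE of the same window."""
    return shannon_entropy(window) - relative_entropy(window, window_size)


def pseudo_accessibility(sequence: str, smooth: int = 5) -> np.ndarray:
    """Deterministic hydropathy-based stand-in for predicted accessibility.

    Per-residue complement of the Eisenberg scale rescaled to [0, 1]
    (hydrophilic -> high), then averaged over a centered ``smooth``-residue
    moving window (truncated at the termini). Placeholders score 0. This is
    a rough built-in substitute for a real accessibility predictor and its
    use is recorded in model metadata.
    """
    idx = encode_indices(sequence)
    h = EISENBERG_VEC
    hmin, hmax = h[:N_AA].min(), h[:N_AA].max()
    comp = (hmax - EISENBERG_VEC[idx]) / (hmax - hmin)
    comp[idx == X_INDEX] = 0.0
    half = smooth // 2
    out = np.empty_like(comp)
    for i in range(len(comp)):
        lo, hi = max(0, i - half), min(len(comp), i + half + 1)
        out[i] = comp[lo:hi].mean()
    out[idx == X_INDEX] = 0.0
    return out


def asa_features(
    window: str,
    profile_values: Sequence[float] | None = None,
    center_position: int | None = None,
) -> np.ndarray:
    """Per-residue accessibility channel for one window (length w).

    With a profile, the w values at the window's positions are sliced out
    of ``profile_values`` (1-based ``center_position`` required); positions
    overhanging the protein get 0. Without a profile, the documented
    fallback :func:`pseudo_accessibility` of the window string is used.
    """
    w = len(window)
    if profile_values is None:
        return pseudo_accessibility(window)
    if center_position is None:
        raise ValueError("center_position is required when slicing a profile")
    vals = np.asarray(profile_values, dtype=float)
    half = (w - 1) // 2
    out = np.zeros(w, dtype=float)
    for j in range(w):
        pos = center_position - half + j  # 1-based
        if 1 <= pos <= len(vals) and window[j] != "X":
            out[j] = vals[pos - 1]
    return out


def overlapping_properties(window: str) -> np.ndarray:
    """10 membership bits per residue over the overlapping classes (10*w)."""
    return OP_BITS[encode_indices(window)].ravel()


def ach_features(window: str) -> np.ndarray:
    """Mean Eisenberg hydrophobicity of centered subwindows 3,5,...,w.

    Placeholders add 0 to the sum while the subwindow size stays the
    divisor, so terminal windows remain comparable.
    """
    w = len(window)
    h = EISENBERG_VEC[encode_indices(window)]
    center = (w - 1) // 2
    out = []
    for size in range(3, w + 1, 2):
        half = (size - 1) // 2
        out.append(h[center - half : center + half + 1].sum() / size)
    return np.array(out)


def sequence_features(window: str) -> np.ndarray:
    """One-hot identity over the alphabetically ordered 20 letters (20*w)."""
    return ONE_HOT[encode_indices(window)].ravel()


def ctd_encode(window: str, prop: str = "hydrophobicity") -> str:
    """Three-group encoding of a window under one CTD property (X dropped)."""
    idx = encode_indices(window)
    codes = CTD_CODES[prop][idx]
    return "".join(str(c) for c in codes[codes > 0])


def ctd_features(window: str) -> np.ndarray:
    """Composition/transition/distribution descriptors, 21 per property.

    Per property the layout is C1,C2,C3, T12,T13,T23, then for each group
    the scaled positions of its 1st, 25%, 50%, 75% and 100% occurrences.
    Placeholders are excluded from all counts and positions; an absent
    group contributes zeros to its distribution entries.
    """
    idx = encode_indices(window)
    out = np.zeros(CTD_LENGTH)
    pos = 0
    for prop in CTD_PROPERTY_NAMES:
        codes = CTD_CODES[prop][idx]
        codes = codes[codes > 0]
        n = len(codes)
        comp = np.zeros(3)
        trans = np.zeros(3)
        dist = np.zeros(15)
        if n:
            for g in (1, 2, 3):
                comp[g - 1] = (codes == g).sum() / n
        if n >= 2:
            pairs = list(zip(codes[:-1], codes[1:]))
            for t, (r, s) in enumerate(((1, 2), (1, 3), (2, 3))):
                trans[t] = sum(1 for a, b in pairs if {a, b} == {r, s}) / (n - 1)
        if n:
            for g in (1, 2, 3):
                where = np.flatnonzero(codes == g) + 1  # 1-based
                m = len(where)
                if m == 0:
                    continue
                ranks = [1] + [max(1, math.ceil(q * m)) for q in (0.25, 0.5, 0.75, 1.0)]
                dist[(g - 1) * 5 : g * 5] = [where[r - 1] / n * 100.0 for r in ranks]
        out[pos : pos + 21] = np.concatenate([comp, trans, dist])
        pos += 21
    return out


def _coupling_numbers(idx: np.ndarray, dist: np.ndarray, maxlag: int) -> np.ndarray:
    """tau_k = sum over i of d(s_i, s_{i+k})^2 for k = 1..maxlag.

    Pairs involving a placeholder contribute 0 (its distance row is 0),
    and lags with no residue pairs are 0.
    """
    n = len(idx)
    tau = np.zeros(maxlag)
    for k in range(1, min(maxlag, n - 1) + 1):
        d = dist[idx[:-k], idx[k:]]
        tau[k - 1] = (d * d).sum()
    return tau


def socn_features(window: str) -> np.ndarray:
    """Sequence-order coupling numbers: lags 1..30 under each of the two
    physicochemical distance matrices (hydropathy then Grantham), 60 values."""
    idx = encode_indices(window)
    return np.concatenate(
        [_coupling_numbers(idx, d, SOCN_MAXLAG) for _, d in DISTANCE_MATRICES]
    )


def qso_features(window: str) -> np.ndarray:
    """Quasi-sequence-order descriptors, 100 values.

    Positions 1-20: residue frequencies f_i normalized by
    sum(f) + 0.1 * sum(tau) (first matrix). Positions 21-100: the
    sequence-order terms 0.1 * tau_k / (sum(f) + 0.1 * sum(tau)) for
    k = 1..40 under each matrix. An all-placeholder window yields zeros.
    """
    idx = encode_indices(window)
    freqs = np.bincount(idx[idx != X_INDEX], minlength=N_AA).astype(float)
    fsum = freqs.sum()
    taus = [_coupling_numbers(idx, d, QSO_MAXLAG) for _, d in DISTANCE_MATRICES]
    parts = []
    denom0 = fsum + QSO_WEIGHT * taus[0].sum()
    parts.append(freqs / denom0 if denom0 > 0 else np.zeros(N_AA))
    for tau in taus:
        denom = fsum + QSO_WEIGHT * tau.sum()
        parts.append(QSO_WEIGHT * tau / denom if denom > 0 else np.zeros(QSO_MAXLAG))
    return np.concatenate(parts)


def encode(
    window: str,
    schema: FeatureSchema | None = None,
    asa_values: Sequence[float] | None = None,
    center_position: int | None = None,
) -> FeatureVector:
    """Encode one window string into the full descriptor vector.

    ``asa_values`` is the residue-accessibility profile of the window's
    protein (with ``center_position`` locating the window in it); when
    omitted the built-in pseudo-accessibility fallback is used.
    """
    if schema is None:
        schema = FeatureSchema.for_window(len(window))
    w = schema.window_size
    if len(window) != w:
        raise ValueError(f"window length {len(window)} != schema window size {w}")
    parts = {
        "H": np.array([shannon_entropy(window)]),
        "RE": np.array([relative_entropy(window, w)]),
        "IG": np.array([information_gain(window, w)]),
        "ASA": asa_features(window, asa_values, center_position),
        "OP": overlapping_properties(window),
        "ACH": ach_features(window),
        "SF": sequence_features(window),
        "CTD": ctd_features(window),
        "SOCN": socn_features(window),
        "QSO": qso_features(window),
    }
    lengths = family_lengths(w)
    for fam, arr in parts.items():
        if len(arr) != lengths[fam]:
            raise RuntimeError(
                f"{fam} produced {len(arr)} values, schema expects {lengths[fam]}"
            )
    return FeatureVector(schema, np.concatenate([parts[f] for f in FAMILY_ORDER]))


def encode_windows(
    windows: Iterable["SequenceWindow"],
    asa_profiles: Mapping[str, "AsaProfile"] | None = None,
    schema: FeatureSchema | None = None,
) -> tuple[np.ndarray, np.ndarray, FeatureSchema, bool]:
    """Encode a batch of windows into a feature matrix.

    Returns (X, y, schema, used_fallback) where y is 1 for positive
    windows and ``used_fallback`` records whether any window lacked a
    real accessibility profile.
    """
    windows = list(windows)
    if not windows:
        raise ValueError("no windows to encode")
    if schema is None:
        schema = FeatureSchema.for_window(len(windows[0].residues))
    used_fallback = False
    rows = []
    labels = []
    for win in windows:
        profile = None
        if asa_profiles is not None:
            profile = asa_profiles.get(win.protein_id)
        if profile is None:
            used_fallback = True
            vec = encode(win.residues, schema)
        else:
            vec = encode(
                win.residues,
                schema,
                asa_values=profile.values,
                center_position=win.center_position,
            )
        rows.append(vec.values)
        labels.append(1 if win.label == "positive" else 0)
    return np.vstack(rows), np.array(labels, dtype=int), schema, used_fallback
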