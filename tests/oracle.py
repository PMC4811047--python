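"""Independent brute-force reference implementations of the descriptor
formulas, written directly from their definitions in plain Python (no
numpy, no shared helpers or tables with the package). Used only to
cross-check the production encoders on small windows.
"""

import math

AA = "ACDEFGHIKLMNPQRSTVWY"

EISENBERG = {
    "A": 0.62, "C": 0.29, "D": -0.90, "E": -0.74, "F": 1.19,
    "G": 0.48, "H": -0.40, "I": 1.38, "K": -1.50, "L": 1.06,
    "M": 0.64, "N": -0.78, "P": 0.12, "Q": -0.85, "R": -2.53,
    "S": -0.18, "T": -0.05, "V": 1.08, "W": 0.81, "Y": 0.26,
}

OP_GROUPS = [
    "NQSDECTKRHYW",  # polar
    "KHR",           # positive
    "DE",            # negative
    "KHRDE",         # charged
    "AGCTIVLKHFWYM", # hydrophobic
    "IVL",           # aliphatic
    "FYWH",          # aromatic
    "PNDTCAGSV",     # small
    "ASGC",          # tiny
    "P",             # proline
]

CTD_GROUPS = [
    ("RKEDQN", "GASTPHY", "CLVIMFW"),      # hydrophobicity
    ("GASTPDC", "NVEQIL", "MHKFRYW"),      # van der Waals volume
    ("LIFWCMVY", "PATGS", "HQRKNED"),      # polarity
    ("GASDT", "CPNVEQIL", "KMHFRYW"),      # polarizability
    ("KR", "ANCQGHILMFPSTWYV", "DE"),      # charge
    ("EALMQKRH", "VIYCWFT", "GNPSD"),      # secondary structure
    ("ALFCGIVW", "RKQEND", "MPSTHY"),      # solvent accessibility
]

GRANTHAM_CPV = {
    # aa: (composition, polarity, volume)
    "A": (0.0, 8.1, 31.0), "R": (0.65, 10.5, 124.0), "N": (1.33, 11.6, 56.0),
    "D": (1.38, 13.0, 54.0), "C": (2.75, 5.5, 55.0), "Q": (0.89, 10.5, 85.0),
    "E": (0.92, 12.3, 83.0), "G": (0.74, 9.0, 3.0), "H": (0.58, 10.4, 96.0),
    "I": (0.0, 5.2, 111.0), "L": (0.0, 4.9, 111.0), "K": (0.33, 11.3, 119.0),
    "M": (0.0, 5.7, 105.0), "F": (0.0, 5.2, 132.0), "P": (0.39, 8.0, 32.5),
    "S": (1.42, 9.2, 32.0), "T": (0.71, 8.6, 61.0), "W": (0.13, 5.4, 170.0),
    "Y": (0.20, 6.2, 136.0), "V": (0.0, 5.9, 84.0),
}


def _strip(window):
    return [c for c in window if c != "X"]


def entropy(window):
    seq = _strip(window)
    if not seq:
        return 0.0
    h = 0.0
    for aa in set(seq):
        p = seq.count(aa) / len(seq)
        h -= p * math.log2(p)
    return h


def relative_entropy(window, window_size=None):
    seq = _strip(window)
    if not seq:
        return 0.0
    w = window_size if window_size is not None else len(window)
    p0 = 1.0 / w
    re = 0.0
    for aa in set(seq):
        p = seq.count(aa) / len(seq)
        re += p * math.log2(p / p0)
    return re


def information_gain(window, window_size=None):
    return entropy(window) - relative_entropy(window, window_size)


def overlapping_properties(window):
    out = []
    for c in window:
        for group in OP_GROUPS:
            out.append(1.0 if c in group else 0.0)
    return out


def ach(window):
    w = len(window)
    mid = (w - 1) // 2
    out = []
    for size in range(3, w + 1, 2):
        half = (size - 1) // 2
        sub = window[mid - half : mid + half + 1]
        out.append(sum(EISENBERG.get(c, 0.0) for c in sub) / size)
    return out


def sequence_features(window):
    out = []
    for c in window:
        for aa in AA:
            out.append(1.0 if c == aa else 0.0)
    return out


def ctd(window):
    out = []
    for groups in CTD_GROUPS:
        codes = []
        for c in _strip(window):
            for g, members in enumerate(groups, start=1):
                if c in members:
                    codes.append(g)
        n = len(codes)
        comp = [codes.count(g) / n if n else 0.0 for g in (1, 2, 3)]
        trans = []
        for r, s in ((1, 2), (1, 3), (2, 3)):
            if n >= 2:
                cnt = sum(
                    1
                    for a, b in zip(codes, codes[1:])
                    if (a == r and b == s) or (a == s and b == r)
                )
                trans.append(cnt / (n - 1))
            else:
                trans.append(0.0)
        dist = []
        for g in (1, 2, 3):
            positions = [i + 1 for i, c in enumerate(codes) if c == g]
            if not positions:
                dist.extend([0.0] * 5)
                continue
            m = len(positions)
            ranks = [1,
                     max(1, math.ceil(0.25 * m)),
                     max(1, math.ceil(0.50 * m)),
                     max(1, math.ceil(0.75 * m)),
                     m]
            dist.extend(positions[r - 1] / n * 100.0 for r in ranks)
        out.extend(comp + trans + dist)
    return out


def hydropathy_distance(a, b):
    vals = list(EISENBERG.values())
    rng = max(vals) - min(vals)
    dmax = rng / rng  # 1 after normalization
    if a == "X" or b == "X":
        return 0.0
    return abs(EISENBERG[a] - EISENBERG[b]) / rng / dmax


def grantham_distance(a, b):
    if a == "X" or b == "X":
        return 0.0

    def raw(x, y):
        cx, px, vx = GRANTHAM_CPV[x]
        cy, py, vy = GRANTHAM_CPV[y]
        return 50.723 * math.sqrt(
            1.833 * (cx - cy) ** 2 + 0.1018 * (px - py) ** 2 + 0.000399 * (vx - vy) ** 2
        )

    dmax = max(raw(x, y) for x in AA for y in AA)
    return raw(a, b) / dmax


def tau(window, dist_fn, k):
    total = 0.0
    for i in range(len(window) - k):
        total += dist_fn(window[i], window[i + k]) ** 2
    return total


def socn(window, maxlag=30):
    out = []
    for fn in (hydropathy_distance, grantham_distance):
        for k in range(1, maxlag + 1):
            out.append(tau(window, fn, k))
    return out


def qso(window, maxlag=40, weight=0.1):
    seq = _strip(window)
    freqs = [seq.count(aa) for aa in AA]
    taus = {}
    for name, fn in (("hyd", hydropathy_distance), ("gra", grantham_distance)):
        taus[name] = [tau(window, fn, k) for k in range(1, maxlag + 1)]
    out = []
    denom0 = sum(freqs) + weight * sum(taus["hyd"])
    for f in freqs:
        out.append(f / denom0 if denom0 > 0 else 0.0)
    for name in ("hyd", "gra"):
        denom = sum(freqs) + weight * sum(taus[name])
        for t in taus[name]:
            out.append(weight * t / denom if denom > 0 else 0.0)
    return out
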