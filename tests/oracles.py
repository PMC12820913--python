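"""Independent brute-force oracles for cross-checking the implementation.

Everything here is deliberately written from scratch with plain character
loops and its own complement table — no imports from hlako's sequence code —
so agreement with the package is a meaningful check.
"""

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def rc(seq: str) -> str:
    return "".join(_COMP.get(b, "N") for b in reversed(seq))


def oracle_enumerate(genomic: str):
    """All 23-nt NGG windows on both strands as plain tuples.

    Tuple layout: (protospacer, pam, strand, window_start, cut).
    """
    out = []
    for ws in range(len(genomic) - 22):
        window = genomic[ws : ws + 23]
        if window[21] == "G" and window[22] == "G":
            out.append((window[:20], window[20:23], "+", ws, ws + 16))
        if window[0] == "C" and window[1] == "C":
            out.append((rc(window[3:23]), rc(window[0:3]), "-", ws, ws + 5))
    out.sort(key=lambda t: (t[3], t[2]))
    return out


def oracle_placements(guide: str, genomic: str, k: int):
    """Every ungapped guide placement with <= k mismatches, both strands.

    Tuple layout: (strand, offset, aligned_seq, pam, frozenset(mismatch
    positions 1..20 with 20 PAM-proximal)). Placements whose PAM context
    runs off the sequence are skipped; non-ACGT bases never match.
    """
    n = len(genomic)
    hits = []
    for o in range(n - 19):
        segment = genomic[o : o + 20]
        # plus strand: guide read left to right, PAM 3' on the plus strand
        if o + 23 <= n:
            mism = {
                i + 1
                for i in range(20)
                if guide[i] != segment[i]
                or guide[i] not in _COMP
                or segment[i] not in _COMP
            }
            if len(mism) <= k:
                hits.append(
                    ("+", o, segment, genomic[o + 20 : o + 23], frozenset(mism))
                )
        # minus strand: guide binds the reverse complement, PAM 5' on plus
        if o >= 3:
            aligned = rc(segment)
            mism = {
                i + 1
                for i in range(20)
                if guide[i] != aligned[i]
                or guide[i] not in _COMP
                or aligned[i] not in _COMP
            }
            if len(mism) <= k:
                hits.append(("-", o, aligned, rc(genomic[o - 3 : o]), frozenset(mism)))
    hits.sort(key=lambda t: (t[1], t[0]))
    return hits


def oracle_pam_functional(pam: str) -> bool:
    return (pam[1] == "G" and pam[2] == "G") or pam == "AGA"


def oracle_divergence(positions, weights) -> float:
    return sum(weights[i - 1] for i in positions)


def oracle_predicts_cleavage(guide: str, genomic: str, k: int, weights, theta) -> bool:
    """Independent re-check: does any placement have a functional PAM and
    divergence below theta?"""
    for _, _, _, pam, mism in oracle_placements(guide, genomic, k):
        if oracle_pam_functional(pam) and oracle_divergence(mism, weights) < theta:
            return True
    return False
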