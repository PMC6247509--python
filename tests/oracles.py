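"""Independent brute-force oracles used to cross-check the matching engine.

These are deliberately naive: degenerate oligos are fully expanded to
concrete sequences and compared by plain Hamming distance, windows are
enumerated one by one.  They share no code with the package's bitmask
scanner.
"""

from itertools import product

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "GC", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
    "I": "ACGT",
}

COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def expand_brute(seq):
    return ["".join(p) for p in product(*(IUPAC[c] for c in seq.upper()))]


def min_hamming(primer, window):
    """Minimum Hamming distance over all concrete expansions of both sides."""
    best = len(primer)
    for p in expand_brute(primer):
        for w in expand_brute(window):
            d = sum(a != b for a, b in zip(p, w))
            best = min(best, d)
            if best == 0:
                return 0
    return best


def revcomp_concrete(seq):
    return "".join(COMP[c] for c in reversed(seq))


def scan_brute(primer, sequence, max_mismatch, orientation="forward"):
    """(1-based start, mismatches) for every window within the allowance,
    by exhaustive window comparison."""
    query = primer if orientation == "forward" else None
    if orientation == "reverse":
        # windows whose reverse complement matches the primer: equivalent to
        # matching each expanded primer's reverse complement on the + strand
        queries = [revcomp_concrete(p) for p in expand_brute(primer)]
    else:
        queries = expand_brute(primer)
    L = len(primer)
    hits = []
    for i in range(len(sequence) - L + 1):
        window = sequence[i:i + L]
        d = min(
            min(
                sum(a != b for a, b in zip(q, w))
                for w in expand_brute(window)
            )
            for q in queries
        )
        if d <= max_mismatch:
            hits.append((i + 1, d))
    return hits
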