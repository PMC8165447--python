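"""Independent brute-force oracles, deliberately sharing no code with the
package implementations they check."""

from itertools import permutations

from Bio.Seq import Seq

BASES = "ACGT"
STOPS = {"TAA", "TAG", "TGA"}


def aa(codon: str) -> str:
    return str(Seq(codon).translate())


def brute_sites(codon: str) -> tuple[float, float]:
    """Fractional synonymous/nonsynonymous sites by direct enumeration of
    all nine single-nucleotide neighbors."""
    s = 0.0
    for pos in range(3):
        syn = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            if alt not in STOPS and aa(alt) == aa(codon):
                syn += 1
        s += syn / 3.0
    return s, 3.0 - s


def brute_differences(a: str, b: str) -> tuple[float, float]:
    """Pathway-averaged differences by explicit enumeration of all k!
    substitution orders, skipping stop-passing pathways when possible."""
    diff = [p for p in range(3) if a[p] != b[p]]
    if not diff:
        return 0.0, 0.0

    def walk(order, count_stops):
        cur = a
        sd = nd = 0.0
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1:]
            if nxt in STOPS:
                if not count_stops:
                    return None
                nd += 1.0
            elif aa(cur) == aa(nxt):
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        return sd, nd

    paths = [w for o in permutations(diff) if (w := walk(o, False)) is not None]
    if not paths:
        paths = [walk(o, True) for o in permutations(diff)]
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


def brute_pair_counts(cds_a: str, cds_b: str):
    """Whole-pair (S, N, Sd, Nd) for two gapless, equal-length CDS."""
    assert len(cds_a) == len(cds_b) and len(cds_a) % 3 == 0
    S_a = S_b = Sd = Nd = 0.0
    n_codons = len(cds_a) // 3
    for i in range(0, len(cds_a), 3):
        ca, cb = cds_a[i:i + 3], cds_b[i:i + 3]
        sa, _ = brute_sites(ca)
        sb, _ = brute_sites(cb)
        S_a += sa
        S_b += sb
        sd, nd = brute_differences(ca, cb)
        Sd += sd
        Nd += nd
    S = (S_a + S_b) / 2.0
    return S, 3.0 * n_codons - S, Sd, Nd
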