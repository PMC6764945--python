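"""Exhaustive gap-run duplex alignment oracle (Waterman-Smith-Beyer
style), independent of the package's three-state affine implementation."""

WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
GU = {("G", "U"), ("U", "G")}


def oracle_score(mirna, site, band=4, wc=2.0, gu=1.0, open_=2.0, ext=1.0):
    m, r = mirna, site[::-1]
    n, sm = len(m), len(r)
    lo = -band - max(0, n - sm)
    hi = band + max(0, sm - n)
    NEG = float("-inf")

    def sub(i, j):
        pair = (m[i - 1], r[j - 1])
        return wc if pair in WC else gu if pair in GU else 0.0

    H = [[NEG] * (sm + 1) for _ in range(n + 1)]
    for j in range(sm + 1):
        H[0][j] = 0.0  # free leading target overhang
    for i in range(1, n + 1):
        for j in range(sm + 1):
            if not (lo <= j - i <= hi):
                continue
            best = NEG
            if j > 0 and H[i - 1][j - 1] > NEG:
                best = H[i - 1][j - 1] + sub(i, j)
            for k in range(1, i + 1):
                if lo <= j - (i - k) <= hi and H[i - k][j] > NEG:
                    best = max(best, H[i - k][j] - (open_ + (k - 1) * ext))
            for k in range(1, j + 1):
                if lo <= (j - k) - i <= hi and H[i][j - k] > NEG:
                    best = max(best, H[i][j - k] - (open_ + (k - 1) * ext))
            H[i][j] = best
    return max(H[n][j] for j in range(sm + 1))
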