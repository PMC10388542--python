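"""Independent brute-force oracles used to validate the package's algorithms.

Everything here is written for clarity over speed and deliberately avoids
the implementation paths under test: exhaustive scans, plain-Python dynamic
programming, and closed-form constructions.
"""

from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGTN", "TGCAN")


def rc(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# Maximal inverted repeat (exhaustive anti-diagonal scan)
# ---------------------------------------------------------------------------


def max_inverted_repeat_len(seq: str, min_len: int = 1) -> int:
    """Length of the longest pair of disjoint exact reverse-complement
    repeats on the circle, by exhaustive scan of all anti-diagonal runs of
    the base-vs-complement equality matrix on the doubled sequence."""
    n = len(seq)
    s2 = seq + seq
    arr = np.frombuffer(s2.encode(), dtype=np.uint8)
    comp = np.frombuffer(s2.translate(_COMP).encode(), dtype=np.uint8)
    m = len(s2)
    best = 0
    # E[i, j] true iff s2[i] pairs with s2[j]; inverted repeats are runs
    # along anti-diagonals i + j = u with i increasing and j decreasing.
    for u in range(2 * m - 1):
        i_lo = max(0, u - m + 1)
        i_hi = min(u, m - 1)
        i = np.arange(i_lo, i_hi + 1)
        eq = arr[i] == comp[u - i]
        if not eq.any():
            continue
        # run-length encode
        padded = np.concatenate([[False], eq, [False]]).astype(int)
        d = np.diff(padded)
        starts = np.flatnonzero(d == 1)
        ends = np.flatnonzero(d == -1)
        for s_idx, e_idx in zip(starts, ends):
            run_i0 = i_lo + s_idx
            run_i1 = i_lo + e_idx - 1  # inclusive
            L_run = run_i1 - run_i0 + 1
            if L_run < min_len:
                continue
            # interval A = [run_i0, run_i1 + 1); B = [u - run_i1, u - run_i0 + 1)
            # try every sub-run length (the maximal disjoint pair may be a
            # prefix of a palindromic run); only the longest feasible matters
            for L in range(min(L_run, n), min_len - 1, -1):
                if L <= best:
                    break
                # slide a window of length L inside the run
                ok = False
                for a_ in range(run_i0, run_i1 + 2 - L):
                    a = a_ % n
                    b = (u - (a_ + L - 1)) % n
                    x, y = min(a, b), max(a, b)
                    if y >= x + L and x + n >= y + L:
                        ok = True
                        break
                if ok:
                    best = max(best, L)
                    break
    return best


# ---------------------------------------------------------------------------
# Affine-gap global alignment (plain-Python Gotoh)
# ---------------------------------------------------------------------------

NEG = float("-inf")


def gotoh_score_and_ops(
    a: str, b: str, match=1, mismatch=-2, gap_open=4, gap_ext=1
):
    """Optimal global affine-gap alignment score and one optimal op string.

    A gap of length L costs gap_open + L * gap_ext.  Plain-Python DP for
    small inputs; ops use '=', 'X', 'I' (b-only), 'D' (a-only).
    """
    m, n = len(a), len(b)
    open_cost = gap_open + gap_ext
    M = [[NEG] * (n + 1) for _ in range(m + 1)]
    Ix = [[NEG] * (n + 1) for _ in range(m + 1)]
    Iy = [[NEG] * (n + 1) for _ in range(m + 1)]
    M[0][0] = 0.0
    for i in range(1, m + 1):
        Ix[i][0] = -gap_open - gap_ext * i
    for j in range(1, n + 1):
        Iy[0][j] = -gap_open - gap_ext * j
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = max(M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1]) + s
            Ix[i][j] = max(
                M[i - 1][j] - open_cost,
                Iy[i - 1][j] - open_cost,
                Ix[i - 1][j] - gap_ext,
            )
            Iy[i][j] = max(
                M[i][j - 1] - open_cost,
                Ix[i][j - 1] - open_cost,
                Iy[i][j - 1] - gap_ext,
            )
    score = max(M[m][n], Ix[m][n], Iy[m][n])
    # traceback
    ops = []
    i, j = m, n
    state = [M[m][n], Ix[m][n], Iy[m][n]].index(score)
    while i > 0 or j > 0:
        if state == 0:
            ops.append("=" if a[i - 1] == b[j - 1] else "X")
            state = [M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1]].index(
                max(M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1])
            )
            i, j = i - 1, j - 1
        elif state == 1:
            ops.append("D")
            if Ix[i][j] == Ix[i - 1][j] - gap_ext:
                state = 1
            elif Ix[i][j] == M[i - 1][j] - open_cost:
                state = 0
            else:
                state = 2
            i -= 1
        else:
            ops.append("I")
            if Iy[i][j] == Iy[i][j - 1] - gap_ext:
                state = 2
            elif Iy[i][j] == M[i][j - 1] - open_cost:
                state = 0
            else:
                state = 1
            j -= 1
        if i == 0 and j > 0:
            state = 2
        elif j == 0 and i > 0:
            state = 1
    ops.reverse()
    rle = []
    for op in ops:
        if rle and rle[-1][0] == op:
            rle[-1] = (op, rle[-1][1] + 1)
        else:
            rle.append((op, 1))
    return score, rle


def score_ops(ops, match=1, mismatch=-2, gap_open=4, gap_ext=1) -> float:
    total = 0.0
    for op, n in ops:
        if op == "=":
            total += match * n
        elif op == "X":
            total += mismatch * n
        else:
            total += -(gap_open + gap_ext * n)
    return total


# ---------------------------------------------------------------------------
# Leftmost placement of an InDel (enumeration)
# ---------------------------------------------------------------------------


def leftmost_indel_position(ref: str, qry: str) -> int:
    """For ref/qry differing by exactly one InDel: smallest 0-based position
    p such that removing/inserting the event at p converts ref into qry.
    """
    if len(ref) == len(qry):
        raise ValueError("sequences do not differ by an InDel")
    longer, shorter = (ref, qry) if len(ref) > len(qry) else (qry, ref)
    L = len(longer) - len(shorter)
    positions = [
        p
        for p in range(len(shorter) + 1)
        if shorter[:p] + longer[p : p + L] + shorter[p:] == longer
    ]
    return min(positions)


# ---------------------------------------------------------------------------
# Tandem unit (exhaustive unit/phase search)
# ---------------------------------------------------------------------------


def brute_tandem_unit(event: str, ref: str, pos0: int, is_deletion: bool):
    """Smallest primitive unit explaining the event with a flanking tandem
    copy, by trying every unit length and checking the flanks directly.
    Returns (unit, n_copies_in_event) or None."""
    L = len(event)
    for u_len in range(1, L + 1):
        if L % u_len:
            continue
        unit = event[:u_len]
        if event != unit * (L // u_len):
            continue
        if any(
            u_len % d == 0 and unit == unit[:d] * (u_len // d)
            for d in range(1, u_len)
        ):
            continue  # not primitive
        right = pos0 + (L if is_deletion else 0)
        if (
            ref[right : right + u_len] == unit
            or (pos0 >= u_len and ref[pos0 - u_len : pos0] == unit)
        ):
            return unit, L // u_len
    return None


# ---------------------------------------------------------------------------
# In-silico PCR (naive all-positions scan)
# ---------------------------------------------------------------------------


def naive_pcr(seq: str, fwd: str, rev: str, max_product: int = 2000):
    """All product lengths on a circular template by checking every pair of
    start positions on both strands (exact matching only)."""
    n = len(seq)
    s2 = seq + seq
    products = set()
    for p_left, p_right in ((fwd, rc(rev)), (rev, rc(fwd))):
        left = [
            i for i in range(n) if s2[i : i + len(p_left)] == p_left
        ]
        right = [
            j
            for j in range(2 * n - len(p_right) + 1)
            if s2[j : j + len(p_right)] == p_right
        ]
        for i in left:
            for j in right:
                if j < i + len(p_left):
                    continue
                product = j + len(p_right) - i
                if product <= min(max_product, n):
                    products.add((i % n, product))
    return sorted(L for _, L in products)


# ---------------------------------------------------------------------------
# Random additive trees
# ---------------------------------------------------------------------------


def random_additive_tree(n_taxa: int, rng: np.random.Generator):
    """A random unrooted binary tree with positive branch lengths and its
    exact leaf-to-leaf path-length (additive) distance matrix."""
    taxa = [f"t{i}" for i in range(n_taxa)]
    # grow by random subdivision: start from a 3-star, attach leaves
    import itertools

    next_internal = [0]

    def new_internal():
        next_internal[0] += 1
        return f"_v{next_internal[0]}"

    edges: dict[frozenset, float] = {}

    def add_edge(u, v):
        edges[frozenset((u, v))] = float(rng.uniform(0.05, 1.0))

    center = new_internal()
    for t in taxa[:3]:
        add_edge(center, t)
    for t in taxa[3:]:
        e = list(edges.keys())[rng.integers(len(edges))]
        u, v = tuple(e)
        w = edges.pop(e)
        mid = new_internal()
        split = float(rng.uniform(0.2, 0.8))
        edges[frozenset((u, mid))] = w * split
        edges[frozenset((mid, v))] = w * (1 - split)
        add_edge(mid, t)
    # all-pairs path lengths by BFS
    adj: dict[str, list[tuple[str, float]]] = {}
    for e, w in edges.items():
        u, v = tuple(e)
        adj.setdefault(u, []).append((v, w))
        adj.setdefault(v, []).append((u, w))

    def dists_from(src):
        out = {src: 0.0}
        stack = [src]
        while stack:
            x = stack.pop()
            for y, w in adj[x]:
                if y not in out:
                    out[y] = out[x] + w
                    stack.append(y)
        return out

    D = np.zeros((n_taxa, n_taxa))
    for i, t in enumerate(taxa):
        d = dists_from(t)
        for j, t2 in enumerate(taxa):
            D[i, j] = d[t2]
    D = (D + D.T) / 2  # remove float summation-order asymmetry
    np.fill_diagonal(D, 0.0)
    # true splits: for each internal edge, leaves on one side
    splits = set()
    for e in edges:
        u, v = tuple(e)
        if u in taxa or v in taxa:
            continue
        # leaves reachable from u without crossing e
        seen = {u, v}
        stack = [u]
        side = set()
        while stack:
            x = stack.pop()
            for y, w in adj[x]:
                if y in seen:
                    continue
                seen.add(y)
                if y.startswith("t"):
                    side.add(y)
                else:
                    stack.append(y)
        if 1 < len(side) < n_taxa - 1:
            other = frozenset(taxa) - side
            splits.add(min(frozenset(side), other, key=lambda s: (len(s), sorted(s))))
    return taxa, D, splits, edges


def simulate_alignment_on_tree(edges: dict, taxa: list[str], n_sites: int,
                               sub_prob_per_unit: float, rng: np.random.Generator):
    """Evolve sequences down a tree: each branch substitutes each site with
    probability length * sub_prob_per_unit (transitions only)."""
    adj: dict[str, list[tuple[str, float]]] = {}
    for e, w in edges.items():
        u, v = tuple(e)
        adj.setdefault(u, []).append((v, w))
        adj.setdefault(v, []).append((u, w))
    bases = np.array(list("ACGT"))
    transition = {"A": "G", "G": "A", "C": "T", "T": "C"}
    root = next(iter(adj))
    seqs = {root: "".join(rng.choice(bases, size=n_sites))}
    stack = [root]
    seen = {root}
    while stack:
        x = stack.pop()
        for y, w in adj[x]:
            if y in seen:
                continue
            seen.add(y)
            p = min(1.0, w * sub_prob_per_unit)
            mask = rng.random(n_sites) < p
            seq = list(seqs[x])
            for idx in np.flatnonzero(mask):
                seq[idx] = transition[seq[idx]]
            seqs[y] = "".join(seq)
            stack.append(y)
    return {t: seqs[t] for t in taxa}
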