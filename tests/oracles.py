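"""Independent oracles the implementation is checked against.

Everything here is written from first principles (exhaustive enumeration,
plain recursion, direct arithmetic) and shares no code with the package's
dynamic-programming or vectorized paths.
"""

from functools import lru_cache


def enumerate_global_affine(a, b, match, mismatch, gap_open, gap_ext):
    """Exhaustive enumeration of ALL global alignments of a and b.

    Walks every monotone path through the edit graph, charging
    gap_open + L * gap_ext per maximal gap run, and returns the maximum
    total score. Exponential: only for tiny strings.
    """
    best = [float("-inf")]

    def step(i, j, score, state):
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            step(i + 1, j + 1, score + s, "M")
        if i < len(a):
            open_cost = gap_ext if state == "X" else gap_open + gap_ext
            step(i + 1, j, score - open_cost, "X")
        if j < len(b):
            open_cost = gap_ext if state == "Y" else gap_open + gap_ext
            step(i, j + 1, score - open_cost, "Y")

    step(0, 0, 0.0, "M")
    return best[0]


def recursive_global_affine(a, b, match, mismatch, gap_open, gap_ext):
    """Memoized three-state recursion for the optimal global affine score.

    An independent re-derivation (top-down, dict-cached) of the affine
    alignment optimum; distinct from the package's bottom-up kernel.
    """

    @lru_cache(maxsize=None)
    def f(i, j, state):
        # best score aligning a[i:] with b[j:], arriving in `state`
        if i == len(a) and j == len(b):
            return 0.0
        options = []
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            options.append(s + f(i + 1, j + 1, "M"))
        if i < len(a):
            cost = gap_ext if state == "X" else gap_open + gap_ext
            options.append(-cost + f(i + 1, j, "X"))
        if j < len(b):
            cost = gap_ext if state == "Y" else gap_open + gap_ext
            options.append(-cost + f(i, j + 1, "Y"))
        return max(options)

    return f(0, 0, "M")


def brute_force_region_scan(windows, seeds, max_gap, min_windows):
    """Direct re-derivation of seed merging over one scaffold's window list.

    windows: list of (start, end); seeds: parallel booleans. Returns
    [(start, end, n_seed_windows)].
    """
    idx = [k for k, s in enumerate(seeds) if s]
    out = []
    run = []
    for k in idx:
        if run and k - run[-1] - 1 > max_gap:
            if len(run) >= min_windows:
                out.append((windows[run[0]][0], windows[run[-1]][1], len(run)))
            run = []
        run.append(k)
    if run and len(run) >= min_windows:
        out.append((windows[run[0]][0], windows[run[-1]][1], len(run)))
    return out


def brute_force_binding_sites(template, primer, max_mismatch, three_prime_exact):
    """All-offsets, both-strand primer scan by direct string comparison."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    rc = "".join(comp[c] for c in reversed(primer))
    k = len(primer)
    sites = []
    for pos in range(len(template) - k + 1):
        win = template[pos : pos + k]
        # plus strand: primer 3' end at the right
        mm = sum(x != y for x, y in zip(win, primer))
        tail_ok = win[k - three_prime_exact :] == primer[k - three_prime_exact :]
        if mm <= max_mismatch and tail_ok:
            sites.append((pos, "+", mm))
        # minus strand: site is revcomp(primer); primer 3' end at the left
        mm = sum(x != y for x, y in zip(win, rc))
        head_ok = win[:three_prime_exact] == rc[:three_prime_exact]
        if mm <= max_mismatch and head_ok:
            sites.append((pos, "-", mm))
    return sorted(sites)


def single_linkage_bands(lengths, resolution):
    """Single-linkage clustering of sorted lengths at a distance threshold."""
    if not lengths:
        return []
    xs = sorted(lengths)
    clusters = [[xs[0]]]
    for x in xs[1:]:
        if min(abs(x - y) for y in clusters[-1]) <= resolution:
            clusters[-1].append(x)
        else:
            clusters.append([x])
    return clusters
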