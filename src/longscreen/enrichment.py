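"""Over-representation statistics for pathways and gene categories.

Pathway enrichment of screen hits uses the upper-tail hypergeometric
probability ``P(X >= k)`` for drawing ``k`` annotated features among ``n``
hits from a universe of ``N`` features of which ``K`` are annotated, with
pathways restricted to sizes ``5 <= K < 100`` after intersection with the
universe.  Overlap of hit lists with curated gene categories (aging,
essential, transcription factor, housekeeping) uses Fisher's exact test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

MIN_SET_SIZE = 5
MAX_SET_SIZE = 99  # "at least 5 but less than 100"


@dataclass
class EnrichmentResult:
    name: str
    N: int
    K: int
    n: int
    k: int
    p: float
    odds_ratio: float
    expected: float


def odds_expected(k: int, n: int, K: int, N: int):
    """Sample odds ratio and expected overlap of a 2x2 enrichment table.

    ``OR = k (N - K - n + k) / ((n - k)(K - k))`` with 0/0 reported as
    infinity; ``expected = n K / N``.
    """
    if not (0 <= k <= min(n, K) and 0 <= n <= N and 0 <= K <= N):
        raise ValueError(f"inconsistent table counts k={k}, n={n}, K={K}, N={N}")
    num = k * (N - K - n + k)
    den = (n - k) * (K - k)
    if den == 0:
        odds = 0.0 if k == 0 else np.inf  # 0/0 convention flagged as infinite
    else:
        odds = num / den
    expected = n * K / N if N else 0.0
    return odds, expected


def hypergeom_pvalue(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail ``P(X >= k)`` under Hypergeometric(N, K, n)."""
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def hypergeom_enrich(hits, annotation: dict, universe,
                     min_size: int = MIN_SET_SIZE,
                     max_size: int = MAX_SET_SIZE) -> pd.DataFrame:
    """Hypergeometric over-representation of ``hits`` in each annotated set.

    Annotation sets are intersected with the universe before the size filter
    (keep ``min_size <= K <= max_size``).  Returns a TSV-ready frame sorted
    by p-value.
    """
    hits = set(hits)
    universe = set(universe)
    stray = hits - universe
    if stray:
        raise ValueError(f"hits outside the universe: {sorted(stray)}")
    N, n = len(universe), len(hits)
    rows = []
    for name in sorted(annotation):
        members = set(annotation[name]) & universe
        K = len(members)
        if not min_size <= K <= max_size:
            continue
        k = len(members & hits)
        odds, expected = odds_expected(k, n, K, N)
        rows.append({"set": name, "N": N, "K": K, "n": n, "k": k,
                     "expected": expected, "odds_ratio": odds,
                     "p": hypergeom_pvalue(k, n, K, N)})
    df = pd.DataFrame(rows, columns=["set", "N", "K", "n", "k", "expected",
                                     "odds_ratio", "p"])
    return df.sort_values(["p", "set"], kind="stable").reset_index(drop=True)


def fisher_overlap(set_a, set_b, background):
    """Two-sided Fisher's exact test for overlap of two feature sets.

    Returns ``(p, odds_ratio)`` where the odds ratio is the sample odds ratio
    of the 2x2 table formed against ``background``.
    """
    background = set(background)
    if not background:
        raise ValueError("background must be nonempty")
    a = set(set_a) & background
    b = set(set_b) & background
    if set(set_a) - background or set(set_b) - background:
        stray = sorted((set(set_a) | set(set_b)) - background)
        raise ValueError(f"features outside the background: {stray}")
    k = len(a & b)
    table = [[k, len(a) - k],
             [len(b) - k, len(background) - len(a) - len(b) + k]]
    _, p = stats.fisher_exact(table, alternative="two-sided")
    odds, _ = odds_expected(k, len(a), len(b), len(background))
    return float(p), odds


def read_gmt(path) -> dict[str, set]:
    """Read GMT gene sets: name <tab> description <tab> member..."""
    sets: dict[str, set] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def write_gmt(sets: dict, path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name in sorted(sets):
            members = "\t".join(sorted(sets[name]))
            fh.write(f"{name}\t{description}\t{members}\n")
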