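"""Gene-set over-representation by the right-tailed Fisher's exact test.

For a gene set with K members on the background of N array genes, of which
n are differentially expressed with k falling in the set, the
over-representation p-value is the hypergeometric upper tail
P(X >= k | N, K, n) — identical to the right-tailed Fisher's exact test of
the 2x2 membership table. BH adjustment is applied across all sets of a
collection.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .io_formats import GeneSetCollection
from .paired_de import bh_adjust


def fisher_right_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if not (0 <= k <= min(K, n) and K <= N and n <= N):
        raise ValidationError(f"inconsistent contingency counts "
                              f"k={k}, K={K}, n={n}, N={N}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich(de_genes, background, collection: GeneSetCollection,
           q_cutoff: float | None = None) -> pd.DataFrame:
    """Over-representation of ``de_genes`` in each set of ``collection``.

    ``de_genes`` must be a subset of ``background``; set members outside the
    background are ignored. Returns one row per gene set (k, K, n, N,
    fisher_p, bh_q, overlap genes) sorted by q then p; with ``q_cutoff``
    only sets at or below the cutoff are returned.
    """
    collection.validate()
    bg = set(background)
    de = set(de_genes)
    if not bg:
        raise ValidationError("empty background")
    if not de:
        raise ValidationError("empty DE gene list")
    if not de <= bg:
        raise ValidationError(f"DE genes outside the background: "
                              f"{sorted(de - bg)[:5]}")
    N, n = len(bg), len(de)
    rows = []
    for name, members in collection.sets.items():
        in_bg = set(members) & bg
        K = len(in_bg)
        overlap = sorted(in_bg & de)
        k = len(overlap)
        p = fisher_right_tail(k, K, n, N) if K else 1.0
        rows.append((name, k, K, n, N, p, ",".join(overlap)))
    out = pd.DataFrame(rows, columns=["set", "k", "K", "n", "N", "fisher_p",
                                      "overlap"]).set_index("set")
    out["bh_q"] = bh_adjust(out["fisher_p"].to_numpy())
    out = out.sort_values(["bh_q", "fisher_p"])
    if q_cutoff is not None:
        out = out[out["bh_q"] <= q_cutoff]
    return out[["k", "K", "n", "N", "fisher_p", "bh_q", "overlap"]]


def make_synthetic_collection(genes, rng, n_sets: int = 20,
                              planted: dict[str, list[str]] | None = None,
                              set_size: tuple[int, int] = (15, 80),
                              planted_fraction: float = 0.6) -> GeneSetCollection:
    """Random gene sets for pipeline demonstrations, optionally with planted
    signal sets drawing ``planted_fraction`` of their members from a given
    gene list (synthetic stand-in for a curated pathway collection)."""
    genes = list(genes)
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    for name, source in (planted or {}).items():
        size = int(rng.integers(*set_size))
        n_src = min(int(round(size * planted_fraction)), len(source))
        members = list(rng.choice(source, size=n_src, replace=False))
        others = [g for g in genes if g not in set(members)]
        members += list(rng.choice(others, size=size - n_src, replace=False))
        sets[f"planted_{name}"] = sorted(members)
        descriptions[f"planted_{name}"] = "synthetic set seeded with planted genes"
    for i in range(n_sets):
        size = int(rng.integers(*set_size))
        sets[f"random_{i:02d}"] = sorted(rng.choice(genes, size=size,
                                                    replace=False))
        descriptions[f"random_{i:02d}"] = "synthetic random set"
    return GeneSetCollection(sets, descriptions).validate()
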