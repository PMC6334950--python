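"""Shared fixtures and independent oracles for the test suite."""

import itertools
import math

import numpy as np
import pytest

from strongion import SyntheticConfig, default_prototypes, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """The default 145-cow synthetic cohort (study conditions, fixed seed)."""
    return generate_cohort(SyntheticConfig(
        prototypes=tuple(default_prototypes()), noise_sd=0.2, seed=42))


def ward_oracle_merges(x: np.ndarray) -> list[tuple[int, int, float, int]]:
    """Brute-force Ward (minimum-variance, Ward.D2) agglomeration.

    At each step every cluster pair's merge cost is evaluated directly from
    the within-cluster sum-of-squares increase,
    d(A, B) = sqrt(2|A||B| / (|A|+|B|)) * ||mean(A) - mean(B)||,
    and the cheapest pair is merged. Independent of any linkage library.
    Returns scipy-compatible merge rows (id_a, id_b, height, size).
    """
    n = len(x)
    clusters: dict[int, list[int]] = {i: [i] for i in range(n)}
    merges = []
    next_id = n
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            ma, mb = x[clusters[a]].mean(axis=0), x[clusters[b]].mean(axis=0)
            na, nb = len(clusters[a]), len(clusters[b])
            d = math.sqrt(2.0 * na * nb / (na + nb)) * float(np.linalg.norm(ma - mb))
            if best is None or d < best[0]:
                best = (d, a, b)
        d, a, b = best
        members = clusters.pop(a) + clusters.pop(b)
        clusters[next_id] = members
        merges.append((a, b, d, len(members)))
        next_id += 1
    return merges


def ward_oracle_labels(x: np.ndarray, k: int) -> np.ndarray:
    """Partition into k clusters by replaying the brute-force merges."""
    n = len(x)
    merges = ward_oracle_merges(x)
    clusters: dict[int, list[int]] = {i: [i] for i in range(n)}
    next_id = n
    for a, b, _, _ in merges[: n - k]:
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    labels = np.empty(n, dtype=int)
    for j, members in enumerate(clusters.values()):
        labels[members] = j
    return labels
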