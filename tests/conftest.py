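"""Shared fixtures and independent oracle implementations.

The oracles here deliberately re-derive results by brute force (explicit
rank residuals, breadth-first flood fill, exhaustive enumeration) and stay
independent of the library code paths they check.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.stats import rankdata

from alphaclust import SourceGrid, generate_cohort


@pytest.fixture
def chain_grid() -> SourceGrid:
    """Five nodes on a 10-mm line; neighbours are consecutive nodes."""
    coords = np.array([[k * 10.0, 0.0, 0.0] for k in range(5)])
    labels = np.array(["left", "left", "mid", "right", "right"], dtype=object)
    return SourceGrid(coords=coords, spacing=10.0, region_labels=labels)


@pytest.fixture
def small_cohort():
    return generate_cohort(
        {"young-E3/E3": 24, "young-E3/E4": 11, "old-E3/E3": 16, "old-E3/E4": 9},
        seed=11,
    )


# ---------------------------------------------------------------------------
# oracles


def oracle_partial_spearman(x, y, z) -> float:
    """Rank x, y, z; residualize the x and y ranks on [1, z-ranks] by least
    squares; return the Pearson correlation of the residuals."""
    rx, ry, rz = rankdata(x), rankdata(y), rankdata(z)
    design = np.column_stack([np.ones(len(rx)), rz])
    ex = rx - design @ np.linalg.lstsq(design, rx, rcond=None)[0]
    ey = ry - design @ np.linalg.lstsq(design, ry, rcond=None)[0]
    return float(ex @ ey / np.sqrt((ex @ ex) * (ey @ ey)))


def oracle_clusters(mask, rho, coords, max_dist, min_steps, min_nodes, policy="trim"):
    """Brute-force flood fill over a signed eligibility mask.

    Returns a list of (frozenset of (node, step) members, mass) after the
    same per-cluster layer filtering the library defines: drop frequency
    layers with fewer than ``min_nodes`` nodes ('trim') or discard the
    cluster if any layer is under-populated ('reject'), then require the
    surviving steps to contain a run of >= ``min_steps`` consecutive steps.
    """
    n_nodes, n_freqs = mask.shape
    neighbors = [[] for _ in range(n_nodes)]
    for i in range(n_nodes):
        for j in range(n_nodes):
            if i != j and np.linalg.norm(coords[i] - coords[j]) <= max_dist:
                neighbors[i].append(j)

    seen = set()
    out = []
    for i in range(n_nodes):
        for f in range(n_freqs):
            if mask[i, f] == 0 or (i, f) in seen:
                continue
            sign = mask[i, f]
            comp = set()
            stack = [(i, f)]
            while stack:
                a, b = stack.pop()
                if (a, b) in comp or mask[a, b] != sign:
                    continue
                comp.add((a, b))
                for bb in (b - 1, b + 1):
                    if 0 <= bb < n_freqs and mask[a, bb] == sign and (a, bb) not in comp:
                        stack.append((a, bb))
                for aa in neighbors[a]:
                    if mask[aa, b] == sign and (aa, b) not in comp:
                        stack.append((aa, b))
            seen |= comp

            counts = {}
            for a, b in comp:
                counts[b] = counts.get(b, 0) + 1
            if policy == "reject":
                if any(c < min_nodes for c in counts.values()):
                    continue
                kept = sorted(counts)
            else:
                kept = sorted(b for b, c in counts.items() if c >= min_nodes)
            # longest run of consecutive retained steps
            best = run = 0
            prev = None
            for b in kept:
                run = run + 1 if prev is not None and b == prev + 1 else 1
                best = max(best, run)
                prev = b
            if best < min_steps:
                continue
            members = frozenset((a, b) for a, b in comp if b in kept)
            mass = float(sum(rho[a, b] for a, b in members))
            out.append((members, mass))
    return out
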