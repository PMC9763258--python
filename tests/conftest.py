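import numpy as np
import pytest

from gevrisk.synthdata import SceneParams, generate_varix_scene


def flood_fill_components(mask: np.ndarray, connectivity: int = 8) -> int:
    """Independent BFS flood-fill component counter (test oracle)."""
    mask = np.asarray(mask, bool)
    seen = np.zeros_like(mask)
    if connectivity == 8:
        steps = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    else:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    n = 0
    h, w = mask.shape
    for r0 in range(h):
        for c0 in range(w):
            if not mask[r0, c0] or seen[r0, c0]:
                continue
            n += 1
            stack = [(r0, c0)]
            seen[r0, c0] = True
            while stack:
                r, c = stack.pop()
                for dr, dc in steps:
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < h and 0 <= cc < w and mask[rr, cc] and not seen[rr, cc]:
                        seen[rr, cc] = True
                        stack.append((rr, cc))
    return n


def eps_graph_components(points: np.ndarray, eps: float) -> list[frozenset]:
    """Brute-force connected components of the eps-neighbourhood graph."""
    n = len(points)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if np.hypot(*(points[i] - points[j])) <= eps:
                parent[find(i)] = find(j)
    groups: dict[int, set] = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(i)
    return [frozenset(g) for g in groups.values()]


@pytest.fixture(scope="session")
def grade2_scene():
    return generate_varix_scene(SceneParams(grade=2, rc_grade=2), seed=7)
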