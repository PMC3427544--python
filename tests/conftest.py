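import numpy as np
import pytest

from athresh import simulation, topology


@pytest.fixture(scope="session")
def replicate08():
    """One simulated replicate at the weakest benchmarked signal level."""
    spec = simulation.SimulationSpec(signal_height=0.08, seed=1234)
    dataset = simulation.simulate_dataset(spec)
    glm = simulation.fit_glm(dataset)
    smoothness = topology.estimate_smoothness(glm.residuals, glm.df)
    return {"spec": spec, "dataset": dataset, "glm": glm,
            "smoothness": smoothness}


@pytest.fixture(scope="session")
def replicate16():
    """A replicate at a comfortably detectable signal level."""
    spec = simulation.SimulationSpec(signal_height=0.16, seed=77)
    dataset = simulation.simulate_dataset(spec)
    glm = simulation.fit_glm(dataset)
    smoothness = topology.estimate_smoothness(glm.residuals, glm.df)
    return {"spec": spec, "dataset": dataset, "glm": glm,
            "smoothness": smoothness}


def flood_fill_components(binary):
    """Brute-force 8/26-connected component count (oracle for labeling)."""
    binary = np.asarray(binary, bool)
    visited = np.zeros_like(binary)
    shape = binary.shape
    offsets = [d for d in np.ndindex(*(3,) * binary.ndim)
               if any(v != 1 for v in d)]
    offsets = [tuple(v - 1 for v in d) for d in offsets]
    count = 0
    for start in zip(*np.nonzero(binary)):
        if visited[start]:
            continue
        count += 1
        stack = [start]
        visited[start] = True
        while stack:
            cur = stack.pop()
            for off in offsets:
                nb = tuple(c + o for c, o in zip(cur, off))
                if all(0 <= n < s for n, s in zip(nb, shape)) \
                        and binary[nb] and not visited[nb]:
                    visited[nb] = True
                    stack.append(nb)
    return count


def brute_force_bh(pvals, q):
    """Step-up rule written out directly (oracle for bh_adjust)."""
    p = np.asarray(pvals, float)
    m = p.size
    order = np.argsort(p)
    k_max = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= rank / m * q:
            k_max = rank
    reject = np.zeros(m, bool)
    reject[order[:k_max]] = True
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, m * p[idx] / rank)
        adj[idx] = running
    return adj, reject
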