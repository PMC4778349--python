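import numpy as np
import pytest

from utrscreen import simulate as sim


@pytest.fixture(scope="session")
def default_layout():
    return sim.ReadLayout()


@pytest.fixture(scope="session")
def default_scheme():
    return sim.SortScheme()


@pytest.fixture(scope="session")
def small_screen():
    """A small end-to-end simulated screen shared across tests.

    200 motifs (20 % activating, 20 % repressive at 1.5 SD), 30 integrations
    per motif, count-level sequencing at 50k reads per library.
    """
    truth = sim.generate_truth(200, (0.2, 0.2, 0.6), 1.5, seed=101)
    cells = sim.simulate_cells(truth, mean_integrations=30, noise_sd=1.0, seed=102)
    pops = sim.gate_and_sort(cells, sim.SortScheme(), seed=103)
    table = sim.sequence_counts(pops, depth=50_000, seed=104)
    return truth, cells, pops, table


def random_alignment_block(rng, length=60, n_rows=4, conserved=True, motif=None):
    """One aligned block: random reference; other rows copy or diverge.

    With ``motif`` given, a DNA copy of it is planted at a random position in
    all rows (a conserved instance).
    """
    bases = np.array(list("ACGT"))
    ref = rng.choice(bases, size=length)
    rows = [ref.copy() for _ in range(n_rows)]
    if not conserved:
        for row in rows[1:]:
            n_mut = rng.integers(1, 6)
            pos = rng.choice(length, size=n_mut, replace=False)
            for p in pos:
                row[p] = rng.choice([b for b in "ACGT" if b != row[p]])
    if motif is not None:
        target = list(motif.upper().replace("U", "T"))
        start = int(rng.integers(0, length - len(target) + 1))
        for row in rows:
            row[start : start + len(target)] = target
    return ["".join(row) for row in rows]
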