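import pytest

from lemslite.fixtures import worked_example
from lemslite.lems_model import resolve_type, standard_library


@pytest.fixture(scope="session")
def stdlib():
    return standard_library()


@pytest.fixture(scope="session")
def hr_type(stdlib):
    """The flattened (inheritance-merged) Hindmarsh-Rose cell type."""
    return resolve_type("HindmarshRose1984Cell", stdlib)


@pytest.fixture()
def hr_network():
    """Fresh worked-example document + simulation spec."""
    return worked_example()


def hr_reference_rhs(state, params, i_syn):
    """Independent hand-coded HR derivative function (SI units).

    Mirrors the published three-variable system directly, without going
    through expression parsing or component flattening: x = v/v_scaling,
    phi = y - a x^3 + b x^2, chi = c - d x^2 - y, rho = s (x - x1) - z,
    iMemb = C v_scaling (phi - z) / 1ms + iSyn; dv/dt = iMemb/C,
    dy/dt = chi/1ms, dz/dt = r rho/1ms.
    """
    v, y, z = state
    msec = 1e-3
    x = v / params["v_scaling"]
    phi = y - params["a"] * x ** 3 + params["b"] * x ** 2
    chi = params["c"] - params["d"] * x ** 2 - y
    rho = params["s"] * (x - params["x1"]) - z
    i_memb = params["C"] * params["v_scaling"] * (phi - z) / msec + i_syn
    return (
        i_memb / params["C"],
        chi / msec,
        params["r"] * rho / msec,
    )


def count_bursts(spike_times, gap_factor=5.0):
    """Cluster spikes into bursts: a gap > gap_factor x the median
    inter-spike interval starts a new burst.  Returns (n_bursts, isis)."""
    if len(spike_times) < 2:
        return len(spike_times), []
    isis = [b - a for a, b in zip(spike_times, spike_times[1:])]
    med = sorted(isis)[len(isis) // 2]
    bursts = 1 + sum(1 for g in isis if g > gap_factor * med)
    return bursts, isis
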