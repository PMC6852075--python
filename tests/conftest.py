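import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_snapshot_result(flags_by_generation, n_hosts=100, k=5, seed=0,
                         record_every=25, x_max=1.0 - 1e-6):
    """Build a synthetic SimulationResult whose recorded snapshots are
    unimodal or bimodal according to `flags_by_generation`:
    a list of (generation, kind) with kind in {"uni", "bi", "narrow"}.

    "bi" places 30% of symbionts near 0.03 and 70% near 0.5 (well-separated
    clusters); "narrow" splits the population into two clusters only 0.04
    apart (drift-scale fine structure, not branching).
    """
    import pandas as pd

    from symcoop.simulate import SimConfig, SimulationResult

    gen_rng = np.random.default_rng(seed)
    snapshots = []
    rows = []
    for gen, kind in flags_by_generation:
        n = n_hosts * k
        if kind == "uni":
            x = gen_rng.normal(0.5, 0.02, n)
        elif kind == "bi":
            n_low = int(0.3 * n)
            x = np.concatenate([
                np.abs(gen_rng.normal(0.03, 0.01, n_low)),
                gen_rng.normal(0.5, 0.02, n - n_low),
            ])
            gen_rng.shuffle(x)
        elif kind == "narrow":
            half = n // 2
            x = np.concatenate([
                gen_rng.normal(0.48, 0.008, half),
                gen_rng.normal(0.52, 0.008, n - half),
            ])
            gen_rng.shuffle(x)
        else:
            raise ValueError(kind)
        traits = np.clip(x, 0.0, x_max).reshape(n_hosts, k)
        snapshots.append((gen, traits))
        rows.append({"generation": gen, "mean_x": traits.mean(),
                     "var_x": traits.var(), "realized_R": np.nan,
                     "n_modes": 1, "frac_horizontal": np.nan})
    cfg = SimConfig(n_hosts=n_hosts, k=k, x_max=x_max,
                    n_generations=max(g for g, _ in flags_by_generation) or 1,
                    record_every=record_every)
    return SimulationResult(config=cfg, summaries=pd.DataFrame(rows),
                            snapshots=snapshots)
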