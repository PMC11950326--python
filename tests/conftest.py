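import numpy as np
import pytest

from socthresh.meta import EffectSize, StudyObservation


def make_obs(mean_trt, mean_ctl, sd_trt=0.2, sd_ctl=0.2, n_trt=4, n_ctl=4,
             initial_soc=10.0, obs_id="o1", study_id="s1", fraction="POC",
             **moderators):
    return StudyObservation(
        study_id=study_id, obs_id=obs_id, fraction=fraction,
        mean_trt=mean_trt, mean_ctl=mean_ctl, sd_trt=sd_trt, sd_ctl=sd_ctl,
        n_trt=n_trt, n_ctl=n_ctl, initial_soc=initial_soc,
        moderators=moderators,
    )


def make_effects(lnrrs, vs, study_ids=None, socs=None, **moderators):
    """Build a list of EffectSize records directly from arrays."""
    n = len(lnrrs)
    study_ids = study_ids or [f"s{i}" for i in range(n)]
    socs = socs if socs is not None else [10.0] * n
    out = []
    for i, (y, v) in enumerate(zip(lnrrs, vs)):
        half = 1.959963984540054 * np.sqrt(v)
        cls = "positive" if y - half > 0 else "negative" if y + half < 0 else "neutral"
        out.append(
            EffectSize(
                study_id=study_ids[i], obs_id=f"o{i}", lnrr=float(y), v=float(v),
                weight=1.0 / float(v), ci_low=float(y - half),
                ci_high=float(y + half), response_class=cls,
                initial_soc=float(socs[i]), moderators=dict(moderators),
            )
        )
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def poc_dataset():
    """One synthetic multi-study dataset under the particulate-fraction
    scenario (threshold planted at 15 g/kg), with effect-size arrays."""
    import socthresh as st

    observations = st.generate_meta_dataset(st.poc_scenario(seed=11))
    effects = st.effect_sizes(observations)
    x = np.array([e.initial_soc for e in effects])
    y = np.array([e.lnrr for e in effects])
    w = np.array([e.weight for e in effects])
    return observations, effects, x, y, w
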