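import numpy as np
import pytest

from vmchoice import tasks_agents as ta


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def lessismore_session():
    """One deterministic 120-trial cued-choice session."""
    config = ta.LessIsMoreConfig(seed=101)
    agent = ta.SubjectiveAgent()
    return ta.generate_lessismore_session(config, agent, ta.RTModel())


@pytest.fixture
def greedy_session():
    """Session from a near-greedy agent: clean value ordering HV > CV > LV."""
    config = ta.LessIsMoreConfig(seed=202)
    agent = ta.SubjectiveAgent(temperature=1e-4)
    return ta.generate_lessismore_session(config, agent, ta.RTModel(noise_sd=0.0))


def simulate_rw_sequence(alpha, temp, n_trials, rng, n_stimuli=3, v0=0.5):
    """Simulate a choice sequence from a Rescorla-Wagner/softmax agent with
    slowly drifting reward contingencies (shared across test modules)."""
    import numpy as np
    from vmchoice import agents_rl as rl

    agent = rl.RWAgent(rl.RLParams(alpha, temp), n_stimuli=n_stimuli, v0=v0)
    offered = np.empty((n_trials, 2), dtype=int)
    choices = np.empty(n_trials, dtype=int)
    outcomes = np.empty(n_trials)
    p_reward = rng.uniform(0.2, 0.8, n_stimuli)
    for t in range(n_trials):
        off = rng.choice(n_stimuli, 2, replace=False)
        c = agent.choose(off, rng)
        r = float(rng.random() < p_reward[c])
        agent.update(c, r)
        offered[t], choices[t], outcomes[t] = off, c, r
        if t % 40 == 39:  # drifting contingencies keep values moving
            p_reward = np.clip(p_reward + rng.normal(0, 0.2, n_stimuli), 0.1, 0.9)
    return rl.ChoiceSequence(offered=offered, choices=choices, outcomes=outcomes,
                             n_stimuli=n_stimuli)
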