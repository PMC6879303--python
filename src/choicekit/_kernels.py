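"""Compiled per-trial likelihood loops.

The delta-rule / softmax likelihood must be evaluated sequentially (each
trial's choice probability depends on the state left by all previous
trials), so these are plain loops jitted with numba.  Softmax is computed
with max-subtraction so that large inverse temperatures never overflow, and
the chosen-option probability is floored before the log so the negative
log-likelihood is finite everywhere inside the parameter bounds.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def nll_value_kernel(choices, rewards, block_start, n_arms,
                     alpha, beta, alpha_c, beta_c, bias, q0, floor,
                     probs_out):
    """Negative log-likelihood for the value / choice-kernel family.

    Covers Rescorla-Wagner (alpha_c = beta_c = bias = 0), the pure choice
    kernel (alpha = beta = 0), their mixture, and the side-biased variant
    (``bias`` shifts the first option's value inside the softmax).
    ``probs_out`` receives the unfloored per-trial probability of the
    observed choice.
    """
    T = choices.shape[0]
    Q = np.full(n_arms, q0)
    CK = np.zeros(n_arms)
    drive = np.zeros(n_arms)
    nll = 0.0
    for t in range(T):
        if block_start[t]:
            for k in range(n_arms):
                Q[k] = q0
                CK[k] = 0.0
        for k in range(n_arms):
            drive[k] = beta * Q[k] + beta_c * CK[k]
        drive[0] += beta * bias
        m = drive[0]
        for k in range(1, n_arms):
            if drive[k] > m:
                m = drive[k]
        denom = 0.0
        for k in range(n_arms):
            denom += np.exp(drive[k] - m)
        c = choices[t]
        p = np.exp(drive[c] - m) / denom
        probs_out[t] = p
        if p < floor:
            p = floor
        nll -= np.log(p)
        r = rewards[t]
        Q[c] += alpha * (r - Q[c])
        for k in range(n_arms):
            a = 1.0 if k == c else 0.0
            CK[k] += alpha_c * (a - CK[k])
    return nll


@njit(cache=False)
def nll_state_kernel(choices, rewards, stimuli, n_states, n_actions,
                     alpha, beta, q0, floor, probs_out):
    """Negative log-likelihood for stimulus-conditioned delta-rule learners.

    With ``n_states == 1`` (and all stimuli mapped to 0) this is the
    stimulus-blind agent that learns one value per action; with one state
    per stimulus it is the state-based agent with a value per
    (stimulus, action) pair.
    """
    T = choices.shape[0]
    Q = np.full((n_states, n_actions), q0)
    nll = 0.0
    for t in range(T):
        s = stimuli[t] if n_states > 1 else 0
        m = beta * Q[s, 0]
        for k in range(1, n_actions):
            d = beta * Q[s, k]
            if d > m:
                m = d
        denom = 0.0
        for k in range(n_actions):
            denom += np.exp(beta * Q[s, k] - m)
        c = choices[t]
        p = np.exp(beta * Q[s, c] - m) / denom
        probs_out[t] = p
        if p < floor:
            p = floor
        nll -= np.log(p)
        Q[s, c] += alpha * (rewards[t] - Q[s, c])
    return nll


@njit(cache=False)
def simulate_value_kernel(u_choice, u_reward, reward_probs, block_start,
                          n_arms, alpha, beta, alpha_c, beta_c, bias, q0,
                          choices_out, rewards_out):
    """Free simulation for the value / choice-kernel family on a bandit.

    ``u_choice``/``u_reward`` are pre-drawn uniforms (one pair per trial);
    choices are sampled from the softmax by inverse CDF and only the chosen
    arm's reward is realised.
    """
    T = u_choice.shape[0]
    Q = np.full(n_arms, q0)
    CK = np.zeros(n_arms)
    drive = np.zeros(n_arms)
    p = np.zeros(n_arms)
    for t in range(T):
        if block_start[t]:
            for k in range(n_arms):
                Q[k] = q0
                CK[k] = 0.0
        for k in range(n_arms):
            drive[k] = beta * Q[k] + beta_c * CK[k]
        drive[0] += beta * bias
        m = drive[0]
        for k in range(1, n_arms):
            if drive[k] > m:
                m = drive[k]
        denom = 0.0
        for k in range(n_arms):
            p[k] = np.exp(drive[k] - m)
            denom += p[k]
        u = u_choice[t] * denom
        c = n_arms - 1
        acc = 0.0
        for k in range(n_arms):
            acc += p[k]
            if u < acc:
                c = k
                break
        r = 1 if u_reward[t] < reward_probs[t, c] else 0
        choices_out[t] = c
        rewards_out[t] = r
        Q[c] += alpha * (r - Q[c])
        for k in range(n_arms):
            a = 1.0 if k == c else 0.0
            CK[k] += alpha_c * (a - CK[k])


@njit(cache=False)
def simulate_state_kernel(u_choice, stimuli, correct_action, n_states,
                          n_actions, alpha, beta, q0, choices_out,
                          rewards_out):
    """Free simulation for blind/state-based learners on the stimulus task.

    Rewards are deterministic: 1 iff the chosen action is the shown
    stimulus's correct action.
    """
    T = u_choice.shape[0]
    Q = np.full((n_states, n_actions), q0)
    p = np.zeros(n_actions)
    for t in range(T):
        s = stimuli[t] if n_states > 1 else 0
        m = beta * Q[s, 0]
        for k in range(1, n_actions):
            d = beta * Q[s, k]
            if d > m:
                m = d
        denom = 0.0
        for k in range(n_actions):
            p[k] = np.exp(beta * Q[s, k] - m)
            denom += p[k]
        u = u_choice[t] * denom
        c = n_actions - 1
        acc = 0.0
        for k in range(n_actions):
            acc += p[k]
            if u < acc:
                c = k
                break
        r = 1 if c == correct_action[stimuli[t]] else 0
        choices_out[t] = c
        rewards_out[t] = r
        Q[s, c] += alpha * (r - Q[s, c])
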