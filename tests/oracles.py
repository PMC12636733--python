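"""Independent brute-force oracles for the generative agent.

Everything here is computed from first principles with plain Python floats
-- logistic terms, the binomial up-count posterior, and full enumeration of
all (side sequence, orientation sequence, choice) outcomes of a short trial
-- deliberately sharing no code with the package's policy or likelihood
implementations.
"""

import math
from itertools import product


def logistic(x):
    return 1.0 / (1.0 + math.exp(-x))


def posterior_oracle(up, down, levels=(3, 6, 9), n_cs=12):
    raw = [(n / n_cs) ** up * (1 - n / n_cs) ** down for n in levels]
    s = sum(raw)
    return [r / s for r in raw]


def cs_value_oracle(up, down, trial_type, levels=(3, 6, 9), n_cs=12):
    post = posterior_oracle(up, down, levels, n_cs)
    lo, hi = min(levels), max(levels)
    pcs = [(n - lo) / (hi - lo) for n in levels]
    if trial_type == "combined":
        w = [0.25 + 0.5 * p for p in pcs]
    else:
        w = pcs
    return sum(p * wi for p, wi in zip(post, w))


def enumerate_trial_outcomes(params, trial_type, up_left, up_right,
                             v_color_left, v_color_right, max_steps,
                             n_cs=12, levels=(3, 6, 9)):
    """All (sides, orientations, choice) paths of a short trial.

    Returns a dict mapping (sides tuple, orientation tuple, choice) to its
    probability under the chained gather/look/choose policies, with C
    identities marginalized by drawing orientations hypergeometrically from
    the ring's remaining up/down Cs.  Color-value retrieval uses
    t = completed fixations + 1.
    """
    has_color = trial_type == "combined"
    outcomes = {}

    def dv_color_eff(t):
        if not has_color:
            return 0.0
        f = 1.0 - params.tau_color ** t
        return (v_color_right - v_color_left) * f

    def choice_probs(up_l, down_l, up_r, down_r, t):
        if trial_type == "color_only":
            dv = params.omega_color * (v_color_right - v_color_left)
        else:
            dv = (cs_value_oracle(up_r, down_r, trial_type, levels, n_cs)
                  - cs_value_oracle(up_l, down_l, trial_type, levels, n_cs))
            if trial_type == "combined":
                dv += params.omega_color * dv_color_eff(t)
        p_right = logistic(params.beta_choose * dv)
        return {"left": 1.0 - p_right, "right": p_right}

    def recurse(sides, oris, up_l, down_l, up_r, down_r, last, prob):
        k = len(sides)
        t = k + 1
        dvcs = (cs_value_oracle(up_r, down_r, trial_type, levels, n_cs)
                - cs_value_oracle(up_l, down_l, trial_type, levels, n_cs))
        p_cont = logistic(params.alpha_gather
                          + params.beta_dCs * abs(dvcs)
                          + params.beta_dcolor * abs(dv_color_eff(t))
                          + params.beta_time * (1 - params.tau ** t))
        if k >= max_steps:
            p_cont = 0.0  # forced stop, no gather factor
            stop_prob = prob
        else:
            stop_prob = prob * (1.0 - p_cont)
        for choice, pc in choice_probs(up_l, down_l, up_r, down_r, t).items():
            key = (tuple(sides), tuple(oris), choice)
            outcomes[key] = outcomes.get(key, 0.0) + stop_prob * pc
        if k >= max_steps:
            return
        stay = 0.0 if last is None else (1.0 if last == "right" else -1.0)
        p_right = logistic(params.alpha_look_right
                           + params.beta_look_color * dv_color_eff(t)
                           + params.beta_look_Cs * dvcs
                           + params.beta_look_stay * stay)
        for side, p_side in (("left", 1 - p_right), ("right", p_right)):
            if side == "left":
                rem_up = up_left - up_l
                rem_down = (n_cs - up_left) - down_l
            else:
                rem_up = up_right - up_r
                rem_down = (n_cs - up_right) - down_r
            rem = rem_up + rem_down
            for ori, n_rem in ((True, rem_up), (False, rem_down)):
                if n_rem == 0:
                    continue
                p_ori = n_rem / rem
                d = {"up_l": up_l, "down_l": down_l,
                     "up_r": up_r, "down_r": down_r}
                kname = ("up_" if ori else "down_") + side[0]
                d[kname] += 1
                recurse(sides + [side], oris + [ori], d["up_l"], d["down_l"],
                        d["up_r"], d["down_r"], side,
                        prob * p_cont * p_side * p_ori)

    recurse([], [], 0, 0, 0, 0, None, 1.0)
    return outcomes


def identity_sequence_prob(sides, n_cs=12):
    """Probability of one concrete C-identity sequence under uniform
    selection among each side's not-yet-fixated Cs."""
    remaining = {"left": n_cs, "right": n_cs}
    p = 1.0
    for s in sides:
        p *= 1.0 / remaining[s]
        remaining[s] -= 1
    return p


def orientation_multiplicity(sides, oris, up_left, up_right, n_cs=12):
    """Number of concrete C-identity sequences consistent with an
    orientation sequence (falling factorials of the up/down pools)."""
    pools = {("left", True): up_left, ("left", False): n_cs - up_left,
             ("right", True): up_right, ("right", False): n_cs - up_right}
    m = 1
    for s, o in zip(sides, oris):
        m *= pools[(s, o)]
        pools[(s, o)] -= 1
    return m


def all_side_ori_paths(max_len):
    """Every (sides, orientations) pair up to a given length."""
    for k in range(max_len + 1):
        for sides in product(("left", "right"), repeat=k):
            for oris in product((True, False), repeat=k):
                yield sides, oris
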