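"""Architecture search with a recurrent controller trained by REINFORCE.

A small recurrent policy emits one categorical distribution per architecture
hyperparameter position t = 1..T; the choice at t feeds the hidden state that
produces position t+1.  Sampled architectures are trained briefly and their
validation accuracy R ∈ [0, 1] is the reward.  The controller parameters ω
are ascended along the policy-gradient estimate

    (1/K) Σ_k Σ_t ∇_ω log P(a_t | a_{t−1:1}; ω) · (R_k − b)

where K is the batch of sampled architectures and b an exponential moving
average of past rewards, updated after each gradient step.

The controller is deliberately minimal — a single tanh recurrent cell with
per-position input embeddings and per-position softmax heads — because the
search spaces here have at most 15 positions with ≤ 4 options each.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from preictal.archspace import FULL_OPTION_SETS, decode_arch

__all__ = [
    "Controller",
    "SearchConfig",
    "sample_actions",
    "log_prob_actions",
    "reinforce_update",
    "search",
    "ArchitectureSearch",
]


class Controller:
    """Recurrent controller policy over a list of per-position option sets.

    Parameters are initialized near zero, so the untrained policy is close
    to uniform over the space.  ``baseline_b`` is the EMA reward baseline.
    """

    def __init__(self, option_sets=None, hidden: int = 32, seed: int = 0,
                 ema_decay: float = 0.9, lr: float = 0.05, init_scale: float = 0.1):
        self.option_sets = tuple(
            tuple(o) for o in (FULL_OPTION_SETS if option_sets is None else option_sets)
        )
        self.n_options = [len(o) for o in self.option_sets]
        self.T = len(self.option_sets)
        self.hidden = hidden
        self.seed = seed
        self.ema_decay = float(ema_decay)
        self.lr = float(lr)
        self.baseline_b = 0.0
        self.rng = np.random.default_rng(seed)

        r = np.random.default_rng(seed)
        d = hidden
        self.params = {
            "s0": r.normal(0, init_scale, d),
            "W_h": r.normal(0, init_scale, (d, d)),
            "b_h": np.zeros(d),
        }
        for t in range(self.T):
            self.params[f"U{t}"] = r.normal(0, init_scale, (self.n_options[t], d))
            self.params[f"c{t}"] = np.zeros(self.n_options[t])
            if t > 0:
                self.params[f"E{t}"] = r.normal(
                    0, init_scale, (self.n_options[t - 1], d)
                )

    # -- parameter flattening (used by the finite-difference oracle) --------

    def get_flat(self) -> np.ndarray:
        return np.concatenate([self.params[k].ravel() for k in sorted(self.params)])

    def set_flat(self, flat: np.ndarray) -> None:
        i = 0
        for k in sorted(self.params):
            n = self.params[k].size
            self.params[k] = flat[i : i + n].reshape(self.params[k].shape).copy()
            i += n

    # -- policy forward -----------------------------------------------------

    def _step(self, t, a_prev, h_prev):
        p = self.params
        x = p["s0"] if t == 0 else p[f"E{t}"][a_prev]
        h = np.tanh(x + p["W_h"] @ h_prev + p["b_h"])
        logits = p[f"U{t}"] @ h + p[f"c{t}"]
        logits = logits - logits.max()
        prob = np.exp(logits)
        prob /= prob.sum()
        return h, prob

    def distributions(self, actions):
        """Per-position probability vectors along a given action path."""
        h = np.zeros(self.hidden)
        probs = []
        a_prev = None
        for t in range(self.T):
            h, prob = self._step(t, a_prev, h)
            probs.append(prob)
            a_prev = actions[t]
        return probs

    def grad_log_prob(self, actions):
        """∇_ω Σ_t log P(a_t | a_{t−1:1}; ω) for one action string (BPTT)."""
        p = self.params
        h_prev = np.zeros(self.hidden)
        hs, probs, xs_prev_h = [], [], []
        a_prev = None
        for t in range(self.T):
            xs_prev_h.append(h_prev)
            h, prob = self._step(t, a_prev, h_prev)
            hs.append(h)
            probs.append(prob)
            h_prev = h
            a_prev = actions[t]

        g = {k: np.zeros_like(v) for k, v in p.items()}
        dh_carry = np.zeros(self.hidden)
        for t in reversed(range(self.T)):
            dlogits = -probs[t]
            dlogits[actions[t]] += 1.0
            g[f"U{t}"] += np.outer(dlogits, hs[t])
            g[f"c{t}"] += dlogits
            dh = p[f"U{t}"].T @ dlogits + dh_carry
            dpre = dh * (1.0 - hs[t] ** 2)
            g["b_h"] += dpre
            g["W_h"] += np.outer(dpre, xs_prev_h[t])
            if t == 0:
                g["s0"] += dpre
            else:
                g[f"E{t}"][actions[t - 1]] += dpre
            dh_carry = p["W_h"].T @ dpre
        return g


def sample_actions(ctrl: Controller, rng=None):
    """Sample an action string autoregressively; returns (actions, logps)."""
    rng = ctrl.rng if rng is None else rng
    h = np.zeros(ctrl.hidden)
    actions, logps = [], []
    a_prev = None
    for t in range(ctrl.T):
        h, prob = ctrl._step(t, a_prev, h)
        a = int(rng.choice(len(prob), p=prob))
        actions.append(a)
        logps.append(float(np.log(prob[a])))
        a_prev = a
    return actions, logps


def log_prob_actions(ctrl: Controller, actions) -> float:
    probs = ctrl.distributions(actions)
    return float(sum(np.log(p[a]) for p, a in zip(probs, actions)))


def reinforce_update(ctrl: Controller, batch) -> Controller:
    """One policy-gradient ascent step from a batch of (actions, logps, R).

    Updates parameters in place along (1/K) Σ_k Σ_t ∇ log P · (R_k − b),
    then refreshes the EMA baseline with the batch-mean reward.  Returns the
    controller for chaining.
    """
    K = len(batch)
    if K < 1:
        raise ValueError("empty REINFORCE batch")
    total = {k: np.zeros_like(v) for k, v in ctrl.params.items()}
    for actions, _logps, R in batch:
        adv = float(R) - ctrl.baseline_b
        if adv == 0.0:
            continue
        g = ctrl.grad_log_prob(actions)
        for k in total:
            total[k] += adv * g[k]
    for k in ctrl.params:
        ctrl.params[k] += ctrl.lr * total[k] / K
    mean_R = float(np.mean([R for _a, _l, R in batch]))
    ctrl.baseline_b = ctrl.ema_decay * ctrl.baseline_b + (
        1.0 - ctrl.ema_decay
    ) * mean_R
    return ctrl


@dataclass
class SearchConfig:
    """Search budget: K architectures per batch over n_batches updates."""

    K: int = 4
    n_batches: int = 50
    candidate_epochs: int = 3
    controller_hidden: int = 32
    controller_lr: float = 0.05
    ema_decay: float = 0.9
    seed: int = 0

    def __post_init__(self):
        if self.K < 1 or self.candidate_epochs < 1:
            raise ValueError("K and candidate_epochs must be >= 1")


def search(
    reward_fn,
    cfg: SearchConfig,
    option_sets=None,
    log: list | None = None,
):
    """Run the REINFORCE search loop.

    ``reward_fn(actions) -> R`` trains/validates the decoded candidate (or is
    a rigged oracle in tests).  A candidate whose training raises is recorded
    at chance reward (0.5) and the search continues.  ``log`` may carry
    records from a previous run to resume: completed batches are not rerun.

    Returns ``(best_actions, log)``; the log has one record per evaluated
    candidate with its action string and reward.
    """
    option_sets = FULL_OPTION_SETS if option_sets is None else option_sets
    ctrl = Controller(
        option_sets,
        hidden=cfg.controller_hidden,
        seed=cfg.seed,
        ema_decay=cfg.ema_decay,
        lr=cfg.controller_lr,
    )
    log = [] if log is None else list(log)
    done_batches = len(log) // cfg.K
    # replay logged batches to restore controller state deterministically
    for bi in range(done_batches):
        batch = [
            (rec["actions"], None, rec["reward"])
            for rec in log[bi * cfg.K : (bi + 1) * cfg.K]
        ]
        for actions, _l, _r in batch:
            sample_actions(ctrl)  # advance the sampler stream
        reinforce_update(ctrl, batch)

    for bi in range(done_batches, cfg.n_batches):
        batch = []
        for _k in range(cfg.K):
            actions, logps = sample_actions(ctrl)
            try:
                R = float(reward_fn(actions))
            except (FloatingPointError, ValueError):
                R = 0.5  # diverged candidate scores at chance
            batch.append((actions, logps, R))
            log.append({"batch": bi, "actions": list(actions), "reward": R})
        reinforce_update(ctrl, batch)

    best = max(log, key=lambda r: r["reward"])
    return list(best["actions"]), log


class ArchitectureSearch:
    """Estimator-style wrapper: fit(X, y) runs the search on window data.

    Candidates are trained as :class:`~preictal.estimators.QuantizedCNNClassifier`
    on a stratified train/validation split of (X, y); the reward is validation
    accuracy.  Fitted attributes: ``best_arch_``, ``best_actions_``, ``log_``.
    """

    def __init__(self, config: SearchConfig | None = None, option_sets=None,
                 bits: int = 8, val_fraction: float = 0.3):
        self.config = config
        self.option_sets = option_sets
        self.bits = bits
        self.val_fraction = val_fraction

    def get_params(self, deep=True):
        return {
            "config": self.config,
            "option_sets": self.option_sets,
            "bits": self.bits,
            "val_fraction": self.val_fraction,
        }

    def set_params(self, **kw):
        for k, v in kw.items():
            setattr(self, k, v)
        return self

    def fit(self, X, y):
        from sklearn.model_selection import train_test_split

        from preictal.estimators import QuantizedCNNClassifier

        cfg = self.config or SearchConfig()
        option_sets = self.option_sets or FULL_OPTION_SETS
        Xtr, Xva, ytr, yva = train_test_split(
            X, y, test_size=self.val_fraction, stratify=y, random_state=cfg.seed
        )

        def reward(actions):
            arch = decode_arch(actions, option_sets)
            clf = QuantizedCNNClassifier(
                arch=arch,
                bits=self.bits,
                epochs=cfg.candidate_epochs,
                random_state=cfg.seed,
            )
            clf.fit(Xtr, ytr)
            return float(np.mean(clf.predict(Xva) == yva))

        self.best_actions_, self.log_ = search(reward, cfg, option_sets)
        self.best_arch_ = decode_arch(self.best_actions_, option_sets)
        return self
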