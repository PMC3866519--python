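"""System competition: trust weights, response selection, feedback routing.

Trust in the explicit system, theta_E (theta_P = 1 - theta_E), starts at
0.99 — people walk into a categorization task rule-first — and is nudged
every trial by the *suggested* explicit response's correctness:

    correct:  theta_E <- theta_E + Delta_OC (1 - theta_E)
    error:    theta_E <- theta_E - Delta_OE theta_E

which keeps theta_E in [0, 1] by construction.  Under soft switching the
emitted response comes from the explicit system iff

    theta_E |h_E| >= theta_P |h_P|

(the tie goes to the rule-preferring explicit system); under the
hard-never-switch regime the explicit system emits every response, which
is the worst case for procedural learning and isolates what the
procedural system can learn while it never controls behavior.

Feedback routing distinguishes the two feedback architectures: with
*independent* feedback the procedural learner is rewarded according to
its own suggestion's correctness on every trial regardless of who
responded; with *single* feedback it receives the feedback elicited by
the emitted (observable) response.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .dopamine import D_BASE
from .procedural import LearningParams

__all__ = [
    "THETA_E_INIT",
    "ArbitrationState",
    "ModelConfig",
    "update_system_trust",
    "select_response",
    "route_feedback",
]

THETA_E_INIT = 0.99

FEEDBACK_MODES = ("independent", "single")
SWITCHING_MODES = ("soft", "hard_never_switch")


@dataclass
class ArbitrationState:
    """Trust weights and their learning rates."""

    theta_e: float = THETA_E_INIT
    delta_oc: float = 0.01
    delta_oe: float = 0.01

    @property
    def theta_p(self) -> float:
        return 1.0 - self.theta_e


def update_system_trust(state: ArbitrationState,
                        explicit_correct: bool) -> ArbitrationState:
    """Grow trust toward 1 on explicit-correct trials, decay it otherwise.

    The update keys on the explicit system's *suggested* response on every
    trial, including trials the procedural system controlled.
    """
    if explicit_correct:
        theta = state.theta_e + state.delta_oc * (1.0 - state.theta_e)
    else:
        theta = state.theta_e - state.delta_oe * state.theta_e
    return replace(state, theta_e=theta)


def select_response(theta_e: float, h_e_abs: float, explicit_label: int,
                    theta_p: float, h_p_abs: float, procedural_label: int,
                    ) -> tuple[str, int]:
    """Soft-switch arbitration: trust-weighted confidence comparison.

    Returns ``(controller, emitted_label)`` with controller "explicit" or
    "procedural"; equality of the weighted confidences goes to the
    explicit system.
    """
    if theta_e * h_e_abs >= theta_p * h_p_abs:
        return "explicit", explicit_label
    return "procedural", procedural_label


def route_feedback(feedback_mode: str, controller: str, emitted_correct: bool,
                   procedural_suggestion_correct: bool) -> str:
    """Reward event ("correct"/"error") delivered to the procedural learner."""
    if feedback_mode == "independent":
        return "correct" if procedural_suggestion_correct else "error"
    if feedback_mode == "single":
        return "correct" if emitted_correct else "error"
    raise ValueError(f"unknown feedback mode: {feedback_mode!r}")


@dataclass(frozen=True)
class ModelConfig:
    """Full configuration of one model architecture.

    The named architectures are:

    ==========  ===========  ==================  =========
    name        feedback     switching           bootstrap
    ==========  ===========  ==================  =========
    2FB-SS      independent  soft                no
    1FB-HS      single       hard_never_switch   no
    1FB-SS      single       soft                no
    1FB-HS-B    single       hard_never_switch   yes
    1FB-SS-B    single       soft                yes
    ==========  ===========  ==================  =========

    The independent-feedback/hard-switch combination is rejected (it is
    not a meaningful architecture: with independent feedback the explicit
    controller is irrelevant to procedural learning).

    ``explicit_accuracy`` switches the explicit system from the fitted
    optimal rule (None) to the stochastically degraded responder pinned at
    that accuracy.  ``epochs`` is the number of passes through the
    stimulus sample during training.
    """

    feedback_mode: str = "independent"
    switching_mode: str = "soft"
    bootstrap: bool = False
    learning: LearningParams = field(default_factory=LearningParams)
    alpha_pr: float = 0.07
    d_base: float = D_BASE
    delta_oc: float = 0.01
    delta_oe: float = 0.01
    theta_e_init: float = THETA_E_INIT
    explicit_accuracy: float | None = None
    init_low: float = 0.001
    init_high: float = 0.2
    epochs: int = 32

    def __post_init__(self):
        if self.feedback_mode not in FEEDBACK_MODES:
            raise ValueError(f"unknown feedback mode: {self.feedback_mode!r}")
        if self.switching_mode not in SWITCHING_MODES:
            raise ValueError(f"unknown switching mode: {self.switching_mode!r}")
        if (self.feedback_mode, self.switching_mode) == ("independent",
                                                         "hard_never_switch"):
            raise ValueError("independent feedback with hard switching is "
                             "not a supported architecture")
        if not 0.0 < self.alpha_pr <= 1.0:
            raise ValueError("alpha_pr must be in (0, 1]")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")

    @property
    def name(self) -> str:
        fb = "2FB" if self.feedback_mode == "independent" else "1FB"
        sw = "SS" if self.switching_mode == "soft" else "HS"
        return f"{fb}-{sw}" + ("-B" if self.bootstrap else "")

    @property
    def soft(self) -> bool:
        return self.switching_mode == "soft"

    # Convenience constructors for the named architectures -----------------
    @classmethod
    def model0(cls, **kw) -> "ModelConfig":
        return cls(feedback_mode="independent", switching_mode="soft",
                   bootstrap=False, **kw)

    @classmethod
    def model1(cls, bootstrap: bool = False, **kw) -> "ModelConfig":
        return cls(feedback_mode="single", switching_mode="hard_never_switch",
                   bootstrap=bootstrap, **kw)

    @classmethod
    def model2(cls, bootstrap: bool = False, **kw) -> "ModelConfig":
        return cls(feedback_mode="single", switching_mode="soft",
                   bootstrap=bootstrap, **kw)
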