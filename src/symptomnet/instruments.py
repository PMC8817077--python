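"""Built-in metadata for the DS-II + PHQ-9 instrument pair.

The Demoralization Scale-II has 16 items scored 0-4; the PHQ-9 has 9 items
scored 0-3.  Positively worded DS-II items (value to others, coping,
self-worth) are marked for reverse scoring; the flag set is configurable by
supplying your own metadata, since wording differs across translations.

``STUDY_COMPOSITES`` lists the three redundant item sets that are merged
into latent composite nodes before network estimation (helplessness,
worthlessness, and death/suicidal ideation), reducing 25 raw items to 22
network nodes.  ``REFERENCE_MOMENTS`` holds published marginal means/SDs of
the scored items in a large cancer-patient sample; the synthetic-data
generator calibrates its ordinalization thresholds against them.
"""

from __future__ import annotations

from .data import CombineMethod, CompositeSpec, ItemMeta, Scale

__all__ = [
    "DS2_PHQ9_ITEMS",
    "STUDY_COMPOSITES",
    "REFERENCE_MOMENTS",
    "NODE_MOMENTS",
    "STUDY_COMMUNITIES",
    "study_item_meta",
]


def _ds(code: str, label: str, reverse: bool = False) -> ItemMeta:
    return ItemMeta(code, Scale.DS2, 0, 4, reverse, label)


def _phq(code: str, label: str) -> ItemMeta:
    return ItemMeta(code, Scale.PHQ9, 0, 3, False, label)


#: The 25 raw items in instrument order (16 DS-II followed by 9 PHQ-9).
DS2_PHQ9_ITEMS: tuple[ItemMeta, ...] = (
    _ds("ds_value", "There is no value in what I can offer others", reverse=True),
    _ds("ds_pointless", "My life seems to be pointless"),
    _ds("ds_role", "My role in life has been lost"),
    _ds("ds_control", "I no longer feel emotionally in control"),
    _ds("ds_nohelp", "No one can help me"),
    _ds("ds_selfhelp", "I feel that I cannot help myself"),
    _ds("ds_hopeless", "I feel hopeless"),
    _ds("ds_irritable", "I feel irritable"),
    _ds("ds_cope", "I cope fairly well with life", reverse=True),
    _ds("ds_regret", "I have a lot of regret about my life"),
    _ds("ds_hurt", "I tend to feel hurt easily"),
    _ds("ds_distress", "I feel distressed about what is happening to me"),
    _ds("ds_worth", "I am not a worthwhile person", reverse=True),
    _ds("ds_death", "I would rather not be alive"),
    _ds("ds_isolated", "I feel quite isolated or alone"),
    _ds("ds_trapped", "I feel trapped by what is happening to me"),
    _phq("phq_interest", "Little interest or pleasure in doing things"),
    _phq("phq_down", "Feeling down, depressed, or hopeless"),
    _phq("phq_sleep", "Trouble falling or staying asleep, or sleeping too much"),
    _phq("phq_tired", "Feeling tired or having little energy"),
    _phq("phq_appetite", "Poor appetite or overeating"),
    _phq("phq_failure", "Feeling bad about yourself - or that you are a failure"),
    _phq("phq_concentrate", "Trouble concentrating on things"),
    _phq("phq_motor", "Slowing or agitation"),
    _phq("phq_death", "Thoughts that you would be better off dead"),
)

#: Redundant item sets merged into composite nodes (25 items -> 22 nodes).
STUDY_COMPOSITES: tuple[CompositeSpec, ...] = (
    CompositeSpec("worthless", ("ds_value", "ds_worth"), CombineMethod.LATENT_SCORE),
    CompositeSpec("helpless", ("ds_nohelp", "ds_selfhelp"), CombineMethod.LATENT_SCORE),
    CompositeSpec("death", ("ds_death", "phq_death"), CombineMethod.LATENT_SCORE),
)

#: Marginal (mean, SD) of each scored raw item in the reference sample.
REFERENCE_MOMENTS: dict[str, tuple[float, float]] = {
    "ds_value": (1.63, 0.96),
    "ds_pointless": (0.55, 0.83),
    "ds_role": (0.51, 0.90),
    "ds_control": (0.80, 0.92),
    "ds_nohelp": (0.85, 1.05),
    "ds_selfhelp": (0.92, 1.04),
    "ds_hopeless": (0.58, 0.88),
    "ds_irritable": (1.19, 0.98),
    "ds_cope": (1.04, 0.98),
    "ds_regret": (1.14, 0.94),
    "ds_hurt": (1.33, 1.00),
    "ds_distress": (1.67, 1.09),
    "ds_worth": (1.18, 1.08),
    "ds_death": (0.21, 0.60),
    "ds_isolated": (0.63, 0.93),
    "ds_trapped": (0.89, 1.08),
    "phq_interest": (0.87, 0.86),
    "phq_down": (0.63, 0.72),
    "phq_sleep": (1.33, 1.06),
    "phq_tired": (1.24, 0.93),
    "phq_appetite": (0.84, 0.99),
    "phq_failure": (0.24, 0.54),
    "phq_concentrate": (0.69, 0.81),
    "phq_motor": (0.42, 0.76),
    "phq_death": (0.15, 0.41),
}


def _composite_moments(spec: CompositeSpec) -> tuple[float, float]:
    ms = [REFERENCE_MOMENTS[c] for c in spec.member_codes]
    return (
        sum(m for m, _ in ms) / len(ms),
        sum(s for _, s in ms) / len(ms),
    )


#: Target (mean, SD) for the 22 post-reduction nodes.  Composite nodes use
#: the average of their members' reference moments (the study's composites
#: are factor scores of unshared data, so some marginal target is needed).
NODE_MOMENTS: dict[str, tuple[float, float]] = {
    **{
        c: REFERENCE_MOMENTS[c]
        for c in REFERENCE_MOMENTS
        if not any(c in s.member_codes for s in STUDY_COMPOSITES)
    },
    **{s.new_code: _composite_moments(s) for s in STUDY_COMPOSITES},
}

#: Community membership of the 22 network nodes: 1 loss of hope and meaning,
#: 2 non-specific emotionality, 3 entrapment, 4 depressive symptoms.
STUDY_COMMUNITIES: dict[str, tuple[str, ...]] = {
    "loss_of_hope_and_meaning": (
        "helpless",
        "ds_hopeless",
        "ds_role",
        "death",
        "ds_pointless",
        "worthless",
        "ds_cope",
    ),
    "nonspecific_emotionality": (
        "phq_failure",
        "ds_regret",
        "ds_control",
        "ds_hurt",
        "ds_irritable",
    ),
    "entrapment": ("ds_isolated", "ds_distress", "ds_trapped"),
    "depressive_symptoms": (
        "phq_motor",
        "phq_concentrate",
        "phq_down",
        "phq_interest",
        "phq_appetite",
        "phq_tired",
        "phq_sleep",
    ),
}


def study_item_meta() -> tuple[ItemMeta, ...]:
    """Metadata for the 25 raw DS-II + PHQ-9 items."""
    return DS2_PHQ9_ITEMS
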