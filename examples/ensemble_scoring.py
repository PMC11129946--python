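"""Score variants with the shipped five-component ensemble model.

Each component votes functional (1) or deleterious (0) at its optimized
cutoff; the ensemble score is the weighted vote average in [0, 1], and
scores <= 0.367 are classified deleterious.  Missing component scores
renormalize the weights; fewer than 3 available components yields
NO_CALL.
"""

import pandas as pd

from apf2 import apf2_score, default_model

model = default_model()
print("shipped model components (cutoff, weight):")
for spec, w in model.components:
    print(f"  {spec.name:18s} {spec.operator}{spec.threshold:<8g} w={w:.3f}")
print(f"deleterious cutoff: score <= {model.cutoff}\n")

# raw predictor scores for three illustrative variants
variants = {
    "CYP2C9:p.L90P": {  # every component on its deleterious side
        "AlphaMissense": 0.98, "PROVEAN": -7.1, "MutationAssessor": 3.6,
        "PolyPhen-2": 0.99, "VEST4": 0.91,
    },
    "CYP2D6:p.S486T": {  # every component on the functional side
        "AlphaMissense": 0.05, "PROVEAN": -0.4, "MutationAssessor": 0.7,
        "PolyPhen-2": 0.01, "VEST4": 0.12,
    },
    "CYP2B6:p.Q172H": {  # split votes, two components missing
        "AlphaMissense": 0.30, "PROVEAN": float("nan"),
        "MutationAssessor": 1.1, "PolyPhen-2": float("nan"), "VEST4": 0.55,
    },
}
for vid, scores in variants.items():
    res = apf2_score(pd.Series(scores, name=vid), model)
    print(
        f"{vid:16s} score={res.score if res.score is None else round(res.score, 3)} "
        f"call={res.call} components used={res.n_components_used}"
    )
print(
    "\nScore 0 = unanimously deleterious, 1 = unanimously functional; "
    "intermediate scores weigh the disagreeing components."
)
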