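"""Published validation data for the automated PRT procedure.

Confusion matrices from the original validation of automated against
manual scoring (frame-level for the three behavior classifiers on an
independent annotated set; trial-level for retrieval status on 60 scored
videos). Counts follow the :class:`~pupretrieval.evaluate.ConfusionCounts`
layout: a = manual 0 & predicted 0, b = manual 1 & predicted 0,
c = manual 0 & predicted 1, d = manual 1 & predicted 1. Under the
class-0-positive reporting convention these matrices reproduce the
published accuracy/sensitivity/specificity figures.
"""

from .evaluate import ConfusionCounts

VALIDATION_CONFUSION = {
    "retrieval": ConfusionCounts(a=16, b=2, c=6, d=36),
    "approach": ConfusionCounts(a=24676, b=233, c=157, d=2618),
    "carry": ConfusionCounts(a=26155, b=120, c=76, d=1333),
    "digging": ConfusionCounts(a=14412, b=925, c=3218, d=9129),
}

#: retrieval accuracy CI inputs: 52 agreeing calls out of 60 trials
RETRIEVAL_AGREEMENT = (52, 60)
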