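"""Shared test utilities."""

from haradapt import labels_to_codes, segment
from haradapt.features import featurize_set


def featurize_recording(rec, config=None):
    """Recording -> (X, y-codes) through the standard window/feature path."""
    segs = segment(rec)
    fm = featurize_set(segs, config)
    return fm.X, labels_to_codes(fm.y)
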