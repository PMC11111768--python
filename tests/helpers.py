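"""Small helpers shared across test modules."""

from neuroquant.phantom import PhantomSpec, make_phantom
from neuroquant.preprocess import clip_percentiles, robust_zscore


def normalized_phantom(spec: PhantomSpec):
    """Phantom volume run through the clip + robust-z-score normalisation."""
    vol, tissue, structural = make_phantom(spec)
    img = robust_zscore(clip_percentiles(vol))
    return img, tissue, structural
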