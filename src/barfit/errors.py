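"""Exception types shared across the pipeline."""


class SizingError(ValueError):
    """A request cannot be satisfied at the given sizes (genome too small,
    more insertions than positions, fewer reads than seeded defects...)."""


class GenerationError(RuntimeError):
    """Random generation failed after bounded retries (e.g. barcode collisions)."""


class ConfigurationError(ValueError):
    """Inconsistent run configuration (unknown gene, missing control sample...)."""


class OrientationError(RuntimeError):
    """PCA sign orientation is degenerate (zero mean loadings)."""
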