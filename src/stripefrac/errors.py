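"""Exception hierarchy for stripefrac."""


class StripefracError(Exception):
    """Base class for all stripefrac errors."""


class NewickError(StripefracError):
    """Malformed Newick input (unbalanced parentheses, duplicate or empty
    leaf names, empty string)."""


class TableError(StripefracError):
    """Invalid feature table (duplicate ids, negative counts, malformed
    header, empty result after filtering)."""


class TreeTableMismatchError(StripefracError):
    """Feature ids in the table that do not map to tree tips."""


class VariantError(StripefracError):
    """Invalid UniFrac variant configuration or kernel/variant mismatch."""


class ArtifactError(StripefracError):
    """Invalid or inconsistent distance-matrix artifact."""
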