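"""Exception hierarchy for the phenoforge build pipeline."""


class PhenoforgeError(Exception):
    """Base class for all errors raised by phenoforge."""


class OboParseError(PhenoforgeError):
    """Malformed OBO input; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class GraphStructureError(PhenoforgeError):
    """Ontology graph violates a structural invariant (cycle, dangling reference)."""


class PatternValidationError(PhenoforgeError):
    """Design-pattern file violates the pattern schema."""


class ExpressionError(PhenoforgeError):
    """Malformed or unresolvable class expression."""


class BindingError(PhenoforgeError):
    """Variable bindings incomplete, duplicated, or unlabeled."""


class SelectionError(PhenoforgeError):
    """Invalid selection configuration or traversal request."""


class MintingError(PhenoforgeError):
    """Identifier collision or provenance mismatch during minting."""


class ObsoletionError(PhenoforgeError):
    """Invalid obsoletion request (unknown id, obsolete replacement target)."""


class BuildError(PhenoforgeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")
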