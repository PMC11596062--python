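"""Exception hierarchy for the abcbind pipeline.

Input problems (bad files, bad vocabulary) and computation problems
(ambiguous mappings, failed fits) are kept on separate branches so the
CLI can map them to distinct exit codes.
"""


class AbcbindError(Exception):
    """Base class for all abcbind errors."""


class InputError(AbcbindError):
    """A problem with user-supplied input (files, tables, config)."""


class PoseFormatError(InputError):
    """An ATOM/HETATM or MODEL record could not be parsed."""

    def __init__(self, path, line_number, message):
        self.path = path
        self.line_number = line_number
        super().__init__(f"{path}:{line_number}: {message}")


class EmptyInputError(InputError):
    """A file or table that must carry data is empty."""


class VocabularyError(InputError):
    """An interaction class outside the closed vocabulary."""


class ComputationError(AbcbindError):
    """A well-formed input on which the requested computation fails."""


class UnmappedAtomError(ComputationError):
    """A scaffold template atom has no counterpart in the pose."""


class AmbiguousMappingError(ComputationError):
    """Several geometrically distinct template embeddings exist."""

    def __init__(self, embeddings, message):
        self.embeddings = embeddings
        super().__init__(message)


class MissingScoreError(ComputationError):
    """An operation that needs docking scores met a pose without one."""


class FitError(ComputationError):
    """Nonlinear least squares did not produce a usable fit."""


class EnumerationCapError(ComputationError):
    """Full constellation enumeration would exceed the configured cap."""
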