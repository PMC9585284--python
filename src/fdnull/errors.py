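"""Exception and warning types shared across the package."""


class ValidationError(ValueError):
    """Base class for input-validation failures."""


class DuplicateIdentifierError(ValidationError):
    """A plot or species identifier occurs more than once."""


class NegativeAbundanceError(ValidationError):
    """An abundance cell is negative (percent cover must be >= 0)."""


class EmptyCommunityError(ValidationError):
    """A plot has no species with positive abundance, or a filter removed all species."""


class MissingValueError(ValidationError):
    """A required trait, abundance or competitiveness value is absent."""


class TraitSchemaError(ValidationError):
    """A trait value or definition violates the declared schema."""


class OrdinationError(ValueError):
    """The distance matrix cannot be embedded as requested."""


class DegenerateTraitWarning(UserWarning):
    """A quantitative trait has zero range and contributes nothing to the distance."""


class NonEuclideanWarning(UserWarning):
    """Negative eigenvalues were encountered and not corrected."""


class NoCheckerboardWarning(UserWarning):
    """The occurrence matrix has no swappable 2x2 submatrix; swap returns it unchanged."""
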