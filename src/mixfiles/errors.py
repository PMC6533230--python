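"""Exception hierarchy shared across the package."""


class MixfileError(Exception):
    """Base class for all errors raised by this package."""


class MixfileParseError(MixfileError):
    """Input text is not well-formed JSON."""


class MixfileShapeError(MixfileError):
    """JSON is well formed but a field has the wrong shape (e.g. a
    quantity array whose length is not 2, or contents that is not a list)."""


class MixfileValidationError(MixfileError):
    """A document with hard validation violations was handed to an
    operation that requires a valid document."""

    def __init__(self, violations):
        self.violations = list(violations)
        msgs = "; ".join(f"{v.path}: {v.message}" for v in self.violations)
        super().__init__(f"document has hard violations: {msgs}")


class UnknownUnitError(MixfileError, LookupError):
    """A unit common name that is not one of the 15 standard units."""


class FormulaError(MixfileError, ValueError):
    """A molecular formula (or InChI formula layer) could not be parsed."""


class MInChIFormatError(MixfileError, ValueError):
    """Text is not a well-formed MInChI string."""


class IncompleteMixtureError(MixfileError):
    """A component carries a structure (molfile) but no InChI, so the
    MInChI component layer cannot be assembled. ``paths`` lists the
    offending tree positions as tuples of child indices."""

    def __init__(self, paths):
        self.paths = list(paths)
        super().__init__(
            "components with a molfile but no InChI (run "
            f"normalize_derived_fields with a structure backend first): {self.paths}"
        )


class RuleCycleError(MixfileError):
    """A text-extraction rule kept matching without changing the name."""
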