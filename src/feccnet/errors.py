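"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """An invalid block/network/training configuration."""


class InputError(ValueError):
    """A runtime input (image, mask, dataset) violating a precondition."""


class DataFormatError(IOError):
    """An unreadable or malformed on-disk input (e.g. a broken NIfTI file)."""
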