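"""Exception hierarchy. CLI maps these onto exit codes (config 2, data 3, training 4)."""


class AirsigError(Exception):
    """Base class for all package errors."""


class ConfigError(AirsigError):
    """Invalid configuration value (exit code 2)."""


class DataError(AirsigError):
    """Invalid or inconsistent data (exit code 3)."""


class SchemaError(DataError):
    """Header/column layout does not match the 9-channel schema."""


class ParseError(DataError):
    """Non-numeric cell or otherwise unparseable file content."""


class EmptySignalError(DataError):
    """A signature with fewer than 2 samples."""


class IntegrityError(DataError):
    """Duplicate (subject, round, session) triples or mixed devices in a corpus."""


class StratificationError(DataError):
    """A subject has too few records for a stratified split."""


class EmptyCoalitionError(DataError):
    """Channel projection onto the empty coalition was requested."""


class IncompleteMapError(DataError):
    """Shapley values requested from a characteristic map with missing coalitions."""


class TrainingError(AirsigError):
    """Model training failure (exit code 4)."""


class TrainingDivergedError(TrainingError):
    """NaN loss during training; carries the offending epoch index."""

    def __init__(self, epoch: int):
        self.epoch = epoch
        super().__init__(f"training diverged (non-finite loss) at epoch {epoch}")


class UnsupportedArchitectureError(AirsigError):
    """Operation (e.g. CAM) not available for this architecture."""
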