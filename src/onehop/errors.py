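"""Exception hierarchy shared across the package."""


class OneHopError(Exception):
    """Base class for all package errors."""


class SchemaInvalidError(OneHopError):
    """The schema document violates a structural invariant (cycle, dangling
    parent, inconsistent inverse/canonicity declaration)."""


class UnknownElementError(OneHopError):
    """A category or predicate label is not present in the schema."""


class FormatError(OneHopError):
    """A KGX file could not be parsed; message carries file and line."""


class ConfigError(OneHopError):
    """The build-configuration document is missing or misusing a slot."""


class QueryValidationError(OneHopError):
    """A query graph violates the one-hop structural contract."""


class UnpinnedQueryError(QueryValidationError):
    """Neither query node carries identifiers; the query cannot be anchored."""


class ConstraintError(OneHopError):
    """An attribute constraint is malformed (e.g. invalid regex)."""


class SnapshotError(OneHopError):
    """An index snapshot file is missing, truncated or version-incompatible."""
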