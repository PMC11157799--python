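"""Minimal estimator base class following the scikit-learn parameter protocol."""

import inspect


class BaseEstimator:
    """get_params/set_params over the constructor signature, sklearn-style.

    Subclasses must store every constructor argument under the same name and
    do no work in ``__init__``; fitted state uses trailing-underscore names.
    """

    @classmethod
    def _param_names(cls):
        sig = inspect.signature(cls.__init__)
        return [
            p.name
            for p in sig.parameters.values()
            if p.name != "self" and p.kind != p.VAR_KEYWORD
        ]

    def get_params(self, deep: bool = True) -> dict:
        return {name: getattr(self, name) for name in self._param_names()}

    def set_params(self, **params):
        valid = set(self._param_names())
        for key, value in params.items():
            if key not in valid:
                raise ValueError(
                    f"invalid parameter {key!r} for {type(self).__name__}; "
                    f"valid parameters are {sorted(valid)}"
                )
            setattr(self, key, value)
        return self

    def __repr__(self):
        args = ", ".join(f"{k}={v!r}" for k, v in self.get_params().items())
        return f"{type(self).__name__}({args})"

    def _check_fitted(self, attr: str):
        if not hasattr(self, attr):
            raise RuntimeError(
                f"{type(self).__name__} instance is not fitted; call fit() first"
            )
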