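# File formats

## Recording CSV (one file per subject)

Header row, then one row per 20 Hz sample:

    time_s, pressure, acc_x, acc_y, acc_z, gyro_x, gyro_y, gyro_z,
    euler_roll, euler_pitch, euler_yaw, label

Units: pressure kPa (or volts, declared via `pressure_unit="V"` /
schema, converted on read), acceleration g, gyroscope deg/s, Euler angles
degrees. `label` is one of `SIT STAND LIE WALK RUN UP DOWN` or
`UNLABELED`.

## Cohort manifest (`manifest.json`)

Written by `haradapt simulate`: generator seed, difficulty,
segments-per-class, and per subject its id, child seed, file name and
ground-truth shift (10 gains, 10 offsets, frequency scale).

## Feature CSV (+ `<name>.meta.json` sidecar)

Rows are features (first column `feature` holds the name
`channel.feature`), columns are segments (`seg0`, `seg1`, ...). The
sidecar JSON carries per-segment labels, subject ids and optional domain
tags.

## Predictions CSV

`segment, code, label` — 0-based segment index, 1-based class code, class
name.

## Diagnostics / report JSON

`adapt` writes per-iteration joint-MMD values and (when the target file
is labeled) the accuracy history and final accuracy. `evaluate` writes
accuracy / F-measure / precision / recall (percent, macro) plus the
confusion matrix as counts and row percentages.

## Run config (`run_config.json`)

Every output directory records the resolved command parameters and the
library version so runs can be reproduced exactly.
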