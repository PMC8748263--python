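#!/usr/bin/env Rscript
# Fit the shared synthetic dataset with mgcv::gamm and compare curves with
# the python fit.  Usage: Rscript scripts/crosscheck_mgcv.R scratch/xcheck
suppressMessages(library(mgcv))

args <- commandArgs(trailingOnly = TRUE)
dir <- if (length(args) >= 1) args[[1]] else "scratch/xcheck"

df <- read.csv(file.path(dir, "data.csv"))
df$subject_id <- factor(df$subject_id)
m <- gamm(value ~ s(age, k = 7, bs = "bs") + sex01 + cohort + education,
          random = list(subject_id = ~1), data = df, method = "REML")
s <- summary(m$gam)
cat("mgcv edf:", s$edf, "  s(age).p:", s$s.table[, "p-value"], "\n")
print(s$p.table)
print(VarCorr(m$lme))

py <- read.csv(file.path(dir, "py_curve.csv"))
grid <- data.frame(age = py$age,
                   sex01 = mean(df$sex01),
                   cohort = mean(df$cohort),
                   education = mean(df$education))
pr <- predict(m$gam, grid, se.fit = TRUE)
rms <- sqrt(mean((py$fit - pr$fit)^2))
rel <- rms / sd(df$value)
cat(sprintf("curve RMS diff: %.4f (%.1f%% of outcome SD; target < 5%%)\n",
            rms, 100 * rel))
if (rel < 0.05) cat("CROSSCHECK PASS\n") else cat("CROSSCHECK FAIL\n")
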