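# Independent cross-check: fit the same multilevel phylogenetic
# meta-analytic model with metafor::rma.mv and emit the results as JSON.
# Usage: Rscript metafor_oracle.R data.csv R.csv moderator out.json
args <- commandArgs(trailingOnly = TRUE)
suppressMessages(library(metafor))
suppressMessages(library(jsonlite))

dat <- read.csv(args[1])
R <- as.matrix(read.csv(args[2], row.names = 1, check.names = FALSE))
moderator <- args[3]
dat$tip <- factor(dat$tip_label, levels = rownames(R))

form <- if (moderator == "none") ~1 else as.formula(paste("~", moderator))
res <- rma.mv(
  y, v,
  mods = form,
  random = list(~1 | study_id, ~1 | effect_id, ~1 | tip),
  R = list(tip = R), Rscale = FALSE,
  data = dat, method = "REML",
  control = list(optimizer = "optim", optmethod = "BFGS")
)

out <- list(
  beta = as.numeric(coef(res)),
  se = as.numeric(res$se),
  zval = as.numeric(res$zval),
  sigma2 = as.numeric(res$sigma2),
  loglik = as.numeric(logLik(res)),
  QM = as.numeric(res$QM),
  QMdf = as.numeric(res$QMdf[1]),
  QMp = as.numeric(res$QMp)
)
write(toJSON(out, digits = 12, auto_unbox = TRUE), args[4])
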