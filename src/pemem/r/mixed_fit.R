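# Batch worker for mixed-effects model fits.
# Usage: Rscript mixed_fit.R jobs.json out.json
# jobs.json: list of {data: csv path, formula, family, engine}
# Emits per job: fixed-effect estimates and SEs, random-effect SDs and
# correlations for the subject grouping, residual SD (gaussian), and a
# convergence flag.  Inference (Wald z, p, CIs, odds ratios) is computed on
# the Python side from the estimates and SEs.

suppressMessages({
  library(jsonlite)
})

args <- commandArgs(trailingOnly = TRUE)
jobs <- fromJSON(args[1], simplifyVector = FALSE)
out <- list()

for (i in seq_along(jobs)) {
  job <- jobs[[i]]
  d <- read.csv(job$data)
  fml <- as.formula(job$formula)
  fam <- job$family
  res <- tryCatch({
    if (job$engine == "glmmTMB") {
      suppressMessages(library(glmmTMB))
      m <- if (fam == "binomial") {
        glmmTMB(fml, data = d, family = binomial())
      } else {
        glmmTMB(fml, data = d, family = gaussian())
      }
      co <- summary(m)$coefficients$cond
      vc <- VarCorr(m)$cond
      conv <- isTRUE(m$fit$convergence == 0) && isTRUE(m$sdr$pdHess)
      sigma_res <- if (fam == "gaussian") sigma(m) else NA
      ngrps <- unname(summary(m)$ngrps$cond[1])
    } else {
      suppressMessages(library(lme4))
      m <- if (fam == "binomial") {
        glmer(fml, data = d, family = binomial())
      } else {
        lmer(fml, data = d, REML = FALSE)
      }
      co <- summary(m)$coefficients
      vc <- VarCorr(m)
      conv <- length(m@optinfo$conv$lme4$messages) == 0
      sigma_res <- if (fam == "gaussian") sigma(m) else NA
      ngrps <- unname(ngrps(m)[1])
    }
    g <- vc[[1]]  # subject grouping
    sds <- attr(g, "stddev")
    corr <- attr(g, "correlation")
    list(
      ok = TRUE,
      terms = rownames(co),
      estimate = unname(co[, "Estimate"]),
      se = unname(co[, "Std. Error"]),
      re_terms = names(sds),
      re_sd = unname(sds),
      re_corr = if (is.null(corr)) NULL else unclass(corr),
      sigma = sigma_res,
      converged = conv,
      n_obs = nrow(d),
      n_groups = ngrps
    )
  }, error = function(e) list(ok = FALSE, error = conditionMessage(e)))
  out[[i]] <- res
}

write_json(out, args[2], digits = NA, na = "null", auto_unbox = TRUE)
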