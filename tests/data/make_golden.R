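# Generates tests/data/golden_lme4.json: reference fits of the three
# fixture datasets with lme4/lmerTest/glmer, frozen for the golden tests.
# Run from the repository root: Rscript tests/data/make_golden.R
suppressMessages({library(lme4); library(lmerTest); library(jsonlite)})
out <- list()

d1 <- read.csv("tests/data/synthetic_lmm_fixture.csv")
m1 <- lmer(diversity ~ consistency*literacy + (1|item) + (1+consistency|participant), data=d1, REML=TRUE)
s1 <- summary(m1)$coefficients
vc1 <- as.data.frame(VarCorr(m1))
out$lmm <- list(coef=unname(s1[, "Estimate"]), se=unname(s1[, "Std. Error"]),
                df=unname(s1[, "df"]), t=unname(s1[, "t value"]), p=unname(s1[, "Pr(>|t|)"]),
                terms=rownames(s1), varcorr=vc1, REMLcrit=REMLcrit(m1))

d2 <- read.csv("tests/data/synthetic_glmm_fixture.csv")
d2$session_c <- d2$session - mean(d2$session)
m2 <- glmer(novel ~ session_c*consistency + session_c*literacy + consistency:literacy + (1|participant) + (1|item),
            data=d2, family=binomial)
s2 <- summary(m2)$coefficients
out$glmm <- list(coef=unname(s2[, "Estimate"]), se=unname(s2[, "Std. Error"]),
                 z=unname(s2[, "z value"]), terms=rownames(s2),
                 varcorr=as.data.frame(VarCorr(m2)), logLik=as.numeric(logLik(m2)))

d3 <- read.csv("tests/data/synthetic_distance_fixture.csv")
d3$session_z <- scale(d3$session)[,1]
m3 <- lmer(distance ~ session_z + (1+session_z|participant_a) + (1+session_z|participant_b), data=d3, REML=TRUE)
s3 <- summary(m3)$coefficients
out$distance <- list(coef=unname(s3[, "Estimate"]), se=unname(s3[, "Std. Error"]),
                     df=unname(s3[, "df"]), terms=rownames(s3), REMLcrit=REMLcrit(m3))

write(toJSON(out, digits=10, auto_unbox=TRUE), "tests/data/golden_lme4.json")
cat("done\n")
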